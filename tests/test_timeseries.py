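import numpy as np
import pandas as pd
import pytest

from limnomag.errors import ValidationError
from limnomag.io_tables import CoverageMatrix
from limnomag.timeseries import (
    classify_persistence,
    curate_contigs,
    normalize_coverage,
    series_stats,
    summarize_genomes,
)


def _matrix(values, totals=None, contigs=None, groups=None):
    contigs = contigs or [f"c{i}" for i in range(len(values))]
    n_samples = len(values[0])
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "lake_group": groups or ["ME"] * n_samples,
            "date": pd.date_range("2008-05-01", periods=n_samples, freq="7D"),
            "total_mapped_bases": totals or [1e9] * n_samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CoverageMatrix(
        values=pd.DataFrame(values, index=contigs, columns=samples, dtype=float),
        samples=meta,
    )


def _contig_map(entries):
    return pd.DataFrame(
        [{"contig_id": c, "genome_id": g, "length_bp": l} for c, g, l in entries]
    ).set_index("contig_id")


class TestNormalizeCoverage:
    def test_constant_coverage_equal_depth_stays_constant(self):
        m = _matrix([[5.0, 5.0, 5.0, 5.0]])
        series = normalize_coverage(m, _contig_map([("c0", "G1", 1000)]))
        np.testing.assert_allclose(series["G1"].values, 5.0)

    def test_doubled_library_size_is_corrected(self):
        # constant true abundance; one sample sequenced twice as deep
        m = _matrix([[5.0, 5.0, 10.0]], totals=[1e9, 1e9, 2e9])
        series = normalize_coverage(m, _contig_map([("c0", "G1", 1000)]))
        np.testing.assert_allclose(series["G1"].values, 5.0)

    def test_length_weighted_mean(self):
        m = _matrix([[4.0, 4.0], [8.0, 8.0]], contigs=["a", "b"])
        series = normalize_coverage(m, _contig_map([("a", "G1", 1000), ("b", "G1", 3000)]))
        np.testing.assert_allclose(series["G1"].values, 7.0)

    def test_unassigned_contig_rejected(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            normalize_coverage(m, _contig_map([("other", "G1", 1000)]))

    def test_zero_depth_sample_excluded_with_warning(self, caplog):
        m = _matrix([[5.0, 5.0, 7.0]], totals=[1e9, 1e9, 0.0])
        with caplog.at_level("WARNING"):
            series = normalize_coverage(m, _contig_map([("c0", "G1", 1000)]))
        assert len(series["G1"].values) == 2
        assert "zero mapped bases" in caplog.text

    def test_split_contig_preserves_genome_abundance(self):
        whole = normalize_coverage(
            _matrix([[6.0, 3.0]]), _contig_map([("c0", "G1", 4000)])
        )["G1"].values
        split = normalize_coverage(
            _matrix([[6.0, 3.0], [6.0, 3.0]], contigs=["c0a", "c0b"]),
            _contig_map([("c0a", "G1", 1500), ("c0b", "G1", 2500)]),
        )["G1"].values
        np.testing.assert_allclose(whole, split)

    def test_library_size_perturbation_round_trips(self):
        rng = np.random.default_rng(4)
        true = rng.uniform(1, 10, size=8)
        totals = rng.uniform(5e8, 2e9, size=8)
        ref = np.median(totals)
        raw = true * totals / ref
        m = _matrix([list(raw)], totals=list(totals))
        series = normalize_coverage(m, _contig_map([("c0", "G1", 1000)]))
        np.testing.assert_allclose(series["G1"].values, true, rtol=1e-9)

    def test_group_restriction(self):
        m = _matrix(
            [[5.0, 5.0, 0.0, 0.0], [0.0, 0.0, 2.0, 2.0]],
            contigs=["me_c", "th_c"],
            groups=["ME", "ME", "TH", "TH"],
        )
        series = normalize_coverage(
            m,
            _contig_map([("me_c", "ME1", 1000), ("th_c", "TH1", 1000)]),
            genome_groups={"ME1": "ME", "TH1": "TH"},
        )
        assert len(series["ME1"].values) == 2
        np.testing.assert_allclose(series["TH1"].values, 2.0)


class TestSeriesStats:
    def test_constant_series_has_zero_cv(self):
        median, mean, cv = series_stats(np.array([3.0, 3.0, 3.0]))
        assert (median, mean, cv) == (3.0, 3.0, 0.0)

    def test_bloom_shape_low_median_high_mean(self):
        median, mean, cv = series_stats(np.array([0.0, 0.0, 0.0, 12.0]))
        assert median == 0.0 and mean == 3.0
        assert cv > 150

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 9, size=20)
        _, _, cv1 = series_stats(x)
        _, _, cv2 = series_stats(10 * x)
        assert cv1 == pytest.approx(cv2, abs=1e-9)

    def test_all_zero_series_flagged_undefined(self):
        median, mean, cv = series_stats(np.zeros(5))
        assert mean == 0.0 and cv is None

    def test_requires_two_samples(self):
        with pytest.raises(ValidationError):
            series_stats(np.array([1.0]))


class TestClassifyPersistence:
    @pytest.mark.parametrize(
        "median,cv,expected",
        [
            (0.0, 583.0, "bloom_and_bust"),   # ephemeral eutrophic-lake pattern
            (6.1, 61.0, "persistent"),         # stable bog pattern
            (2.0, 160.0, "indeterminate"),     # large CV but never near-absent
            (0.5, 150.0, "persistent"),        # boundary: CV at threshold
            (1.0, None, "indeterminate"),
        ],
    )
    def test_default_thresholds(self, median, cv, expected):
        assert classify_persistence(median, cv) == expected


class TestCurateContigs:
    def _genome_matrix(self, rng, n_contigs=5, n_samples=12, contaminant=False):
        base = rng.uniform(1, 8) * np.exp(rng.normal(0, 0.5, size=n_samples))
        rows = [base * np.exp(rng.normal(0, 0.05, n_samples)) for _ in range(n_contigs)]
        contigs = [f"c{i}" for i in range(n_contigs)]
        if contaminant:
            rows.append(rng.uniform(1, 8) * np.exp(rng.normal(0, 0.8, n_samples)))
            contigs.append("cX")
        return _matrix(rows, contigs=contigs), contigs

    def test_tracking_contig_not_flagged(self):
        m, contigs = self._genome_matrix(np.random.default_rng(6))
        report = curate_contigs(m, contigs)
        assert not report["flagged"].any()

    def test_anticorrelated_contig_flagged(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        rows = [base, base, [5.0, 4.0, 3.0, 2.0, 1.0]]
        m = _matrix(rows, contigs=["a", "b", "z"])
        report = curate_contigs(m, ["a", "b", "z"])
        assert report.loc["z", "flagged"]
        assert report.loc["z", "reason"] == "low-correlation"
        assert report.loc["z", "r"] == pytest.approx(-1.0)

    def test_constant_contig_flagged_zero_variance(self):
        rows = [[1.0, 2.0, 3.0, 4.0], [1.1, 2.2, 3.1, 4.2], [2.0, 2.0, 2.0, 2.0]]
        m = _matrix(rows, contigs=["a", "b", "z"])
        report = curate_contigs(m, ["a", "b", "z"])
        assert report.loc["z", "reason"] == "zero-variance"

    def test_planted_contaminant_flagged_in_most_simulations(self):
        rng = np.random.default_rng(7)
        hits = 0
        false_flags = 0
        n = 100
        for _ in range(n):
            m, contigs = self._genome_matrix(rng, contaminant=True)
            report = curate_contigs(m, contigs)
            hits += bool(report.loc["cX", "flagged"])
            false_flags += int(report.loc[[c for c in contigs if c != "cX"], "flagged"].sum() > 0)
        assert hits >= 95
        assert false_flags <= 10

    def test_preconditions(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0]] * 2, contigs=["a", "b"])
        with pytest.raises(ValidationError):
            curate_contigs(m, ["a", "b"])


def test_summarize_genomes_dynamics_split(default_cohort):
    from limnomag.timeseries import normalize_coverage

    groups = {g.genome_id: g.lake_group for g in default_cohort.genomes}
    series = normalize_coverage(default_cohort.coverage, default_cohort.contig_map, groups)
    summary = summarize_genomes(series)
    assert set(summary.columns) == {"cov_median", "cov_mean", "cov_cv_pct", "dynamics"}
    assert len(summary) == 19
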