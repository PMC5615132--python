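import numpy as np
import pytest
from scipy.cluster import hierarchy
import pandas as pd

from limnomag.errors import UndefinedStatisticError
from limnomag.io_tables import HitRecord
from limnomag.profiles import (
    GH_SPEC,
    PSCYT_SPEC,
    SULFATASE_SPEC,
    cluster_profiles,
    coding_density,
    correlate,
    count_families,
    density_vector,
    filter_gh_hits,
    top_family_table,
)

from _oracles import oracle_agglomerate_3, oracle_pearson
from conftest import make_contig


class TestCountFamilies:
    def test_counts_and_richness(self):
        genes = make_contig("G1", "c1", [{"ann": ["GH2"]}, {"ann": ["GH2"]}, {"ann": ["GH29"]}])
        prof = count_families(genes, GH_SPEC)
        assert prof.counts["G1"] == {"GH2": 2, "GH29": 1}
        assert prof.richness("G1") == 2
        assert prof.total("G1") == 3

    def test_no_matches_yields_empty_profile(self):
        genes = make_contig("G1", "c1", [{"ann": ["K00001"]}, {}])
        prof = count_families(genes, GH_SPEC)
        assert prof.counts["G1"] == {}
        assert prof.richness("G1") == 0

    def test_chimeric_gene_counts_once_per_family_once_in_total(self):
        genes = make_contig("G1", "c1", [{"ann": ["GH2", "GH29"]}])
        prof = count_families(genes, GH_SPEC)
        assert prof.counts["G1"] == {"GH2": 1, "GH29": 1}
        assert prof.total("G1") == 1

    def test_planted_counts_recovered_exactly_without_dropout(self, clean_cohort):
        prof = count_families(
            clean_cohort.genes, GH_SPEC, [g.genome_id for g in clean_cohort.genomes]
        )
        for gid, gt in clean_cohort.truth.genomes.items():
            assert prof.counts[gid] == gt.gh_family_counts

    def test_richness_and_total_grow_under_gene_addition(self):
        base = make_contig("G1", "c1", [{"ann": ["GH2"]}])
        more = make_contig("G1", "c2", [{"ann": ["GH29"]}, {"ann": ["GH2"]}])
        p1 = count_families(base, GH_SPEC)
        p2 = count_families(base + more, GH_SPEC)
        assert p2.richness("G1") >= p1.richness("G1")
        assert p2.total("G1") >= p1.total("G1")
        assert p2.richness("G1") <= p2.total("G1")


class TestCodingDensity:
    def test_zero_members(self):
        assert coding_density(0, 1000) == 0.0

    @pytest.mark.parametrize("total,genes,expected", [(40, 1000, 4.0), (119, 2975, 4.0)])
    def test_arithmetic(self, total, genes, expected):
        assert coding_density(total, genes) == pytest.approx(expected)

    def test_zero_gene_count_rejected(self):
        with pytest.raises(ValueError):
            coding_density(5, 0)

    def test_density_stable_under_uniform_subsampling(self, clean_cohort):
        """Random gene dropout leaves the expected density unchanged."""
        rng = np.random.default_rng(0)
        gid = clean_cohort.genomes[-1].genome_id  # a TH genome, GH-rich
        genes = [g for g in clean_cohort.genes if g.genome_id == gid]
        full = count_families(genes, GH_SPEC).total(gid)
        p_full = full / len(genes)
        densities = []
        for _ in range(100):
            keep = rng.random(len(genes)) < 0.5
            sub = [g for g, k in zip(genes, keep) if k]
            densities.append(coding_density(count_families(sub, GH_SPEC).total(gid), len(sub)))
        # binomial s.e. of the subsampled GH count, propagated to percent
        se = 100 * np.sqrt(p_full * (1 - p_full) / (0.5 * len(genes)))
        assert abs(np.mean(densities) - 100 * p_full) < 3 * se


class TestHitFiltering:
    def test_gh109_rule(self):
        hits = [
            HitRecord("ok", "s", 1e-8, 80.0),
            HitRecord("bad_evalue", "s", 1e-5, 80.0),
            HitRecord("bad_coverage", "s", 1e-8, 40.0),
        ]
        assert filter_gh_hits(hits, "gh109") == ["ok"]

    def test_hmm_default_rule_ignores_coverage(self):
        hits = [HitRecord("q1", "s", 1e-8, 10.0), HitRecord("q2", "s", 1e-6, 90.0)]
        assert filter_gh_hits(hits, "hmm_default") == ["q1"]

    def test_one_acceptance_per_query(self):
        hits = [HitRecord("q", "s1", 1e-8, 80.0), HitRecord("q", "s2", 1e-9, 80.0)]
        assert filter_gh_hits(hits, "gh109") == ["q"]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            filter_gh_hits([], "blast_default")


class TestCorrelate:
    def test_identity_and_reversal(self):
        r, p = correlate([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)
        r, _ = correlate([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        r, p = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_matches_brute_force_to_1e12(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, _ = correlate(x, y)
            assert r == pytest.approx(oracle_pearson(list(x), list(y)), abs=1e-12)

    def test_spearman_available(self):
        r, _ = correlate([1, 2, 3, 4], [1, 4, 9, 16], method="spearman")
        assert r == pytest.approx(1.0)


class TestClustering:
    def test_identical_profiles_merge_at_height_zero(self):
        m = pd.DataFrame(
            [[1, 2, 3], [1, 2, 3], [5, 1, 0]],
            index=["a", "b", "c"],
            columns=["GH1", "GH2", "GH3"],
        )
        res = cluster_profiles(m, distance="bray_curtis")
        assert res.merges.iloc[0]["height"] == pytest.approx(0.0)
        assert {res.merges.iloc[0]["left"], res.merges.iloc[0]["right"]} == {"a", "b"}

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    def test_three_genome_merge_order_matches_brute_force(self, linkage):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = pd.DataFrame(
                rng.integers(0, 20, size=(3, 6)).astype(float) + rng.random((3, 6)),
                index=["a", "b", "c"],
            )
            res = cluster_profiles(m, distance="bray_curtis", linkage=linkage)
            from scipy.spatial.distance import pdist

            d01, d02, d12 = pdist(m.to_numpy(), metric="braycurtis")
            pair, h1, h2 = oracle_agglomerate_3(d01, d02, d12, linkage)
            assert res.merges.iloc[0]["height"] == pytest.approx(h1)
            assert {res.merges.iloc[0]["left"], res.merges.iloc[0]["right"]} == {
                ["a", "b", "c"][i] for i in pair
            }
            assert res.merges.iloc[1]["height"] == pytest.approx(h2)

    def test_planted_group_contrast_forms_top_bipartition(self, clean_cohort):
        prof = count_families(
            clean_cohort.genes, GH_SPEC, [g.genome_id for g in clean_cohort.genomes]
        )
        frame = prof.to_frame()
        res = cluster_profiles(frame, distance="bray_curtis", linkage="average")
        labels = hierarchy.fcluster(res.linkage_matrix, t=2, criterion="maxclust")
        split = {}
        for gid, lab in zip(sorted(frame.index), labels):
            split.setdefault(lab, set()).add(gid[:2])
        # ME (distinct GH family palette) separates from the bog groups
        assert any(groups == {"ME"} for groups in split.values())

    def test_constant_profile_under_correlation_suggests_bray_curtis(self):
        m = pd.DataFrame([[0, 0, 0], [1, 2, 3]], index=["a", "b"])
        with pytest.raises(UndefinedStatisticError, match="bray_curtis"):
            cluster_profiles(m, distance="correlation")


def test_top_family_table_totals_and_richness(clean_cohort):
    prof = count_families(
        clean_cohort.genes, GH_SPEC, [g.genome_id for g in clean_cohort.genomes]
    )
    table = top_family_table(prof, n_top=10)
    assert table.shape[1] == 12
    gid = clean_cohort.genomes[0].genome_id
    assert table.loc[gid, "total_GH"] == prof.total(gid)
    assert table.loc[gid, "n_GH_families"] == prof.richness(gid)


def test_density_vector_covers_all_three_classes(clean_cohort):
    counts = {}
    for g in clean_cohort.genes:
        counts[g.genome_id] = counts.get(g.genome_id, 0) + 1
    for spec in (GH_SPEC, SULFATASE_SPEC, PSCYT_SPEC):
        prof = count_families(clean_cohort.genes, spec, counts)
        dv = density_vector(prof, counts)
        assert ((dv >= 0) & (dv <= 100)).all()
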