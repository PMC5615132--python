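"""Coverage normalization, abundance statistics, persistence classification
and temporal-correlation contig curation.

Normalization follows a two-step contract:

1. each sample's coverage depths are scaled by ``reference_depth /
   total_mapped_bases`` where the reference is the median per-sample total
   (library-size correction), then
2. a genome's abundance in a sample is the length-weighted mean of its
   contigs' scaled depths.

Per-genome series are summarized as median, mean and coefficient of
variation (CV%, sample standard deviation over mean) across the date-ordered
samples of the genome's own lake group; the CV separates populations that
persist season-long from "bloom-and-bust" populations that spike once or a
few times and otherwise sit near zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config
from .errors import ValidationError
from .io_tables import CoverageMatrix

logger = logging.getLogger(__name__)

PERSISTENT = "persistent"
BLOOM_AND_BUST = "bloom_and_bust"
INDETERMINATE = "indeterminate"


@dataclass
class AbundanceSeries:
    """Normalized per-sample abundance of one genome, date-ordered."""

    genome_id: str
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def stats(self) -> tuple[float, float, float | None]:
        return series_stats(self.values)


def library_scale_factors(matrix: CoverageMatrix) -> pd.Series:
    """Per-sample scale factor reference_depth / total_mapped_bases.

    Samples with zero total mapped bases are excluded with a warning.
    """
    totals = matrix.samples["total_mapped_bases"].astype(float)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        logger.warning("excluding samples with zero mapped bases: %s", zero)
        totals = totals.drop(zero)
    if totals.empty:
        raise ValidationError("no sample has positive total mapped bases")
    reference = float(totals.median())
    return reference / totals


def normalize_coverage(
    matrix: CoverageMatrix,
    contig_map: pd.DataFrame,
    genome_groups: dict[str, str] | None = None,
) -> dict[str, AbundanceSeries]:
    """Normalize a contig x sample matrix into per-genome abundance series.

    ``contig_map`` is indexed by contig_id with columns genome_id and
    length_bp; every matrix contig must be assigned to exactly one genome.
    When ``genome_groups`` maps genomes to lake groups, each genome's series
    is restricted to its own group's samples (coverage statistics are only
    comparable within one co-assembly's sample set).
    """
    unknown = [c for c in matrix.values.index if c not in contig_map.index]
    if unknown:
        raise ValidationError(f"contigs not assigned to a genome: {unknown}")
    scale = library_scale_factors(matrix)
    kept_samples = [s for s in matrix.values.columns if s in scale.index]
    scaled = matrix.values[kept_samples] * scale[kept_samples]
    out: dict[str, AbundanceSeries] = {}
    for genome_id, sub in contig_map.groupby("genome_id", sort=True):
        contigs = [c for c in sub.index if c in scaled.index]
        if not contigs:
            continue
        weights = sub.loc[contigs, "length_bp"].to_numpy(dtype=float)
        block = scaled.loc[contigs]
        samples = kept_samples
        if genome_groups and genome_id in genome_groups:
            group = genome_groups[genome_id]
            members = set(matrix.group_samples(group))
            samples = [s for s in kept_samples if s in members]
        series = (
            block[samples].to_numpy(dtype=float).T @ weights
        ) / weights.sum()
        out[genome_id] = AbundanceSeries(
            genome_id=genome_id, sample_ids=tuple(samples), values=series
        )
    return out


def series_stats(values: np.ndarray) -> tuple[float, float, float | None]:
    """(median, mean, CV%) of an abundance series.

    CV uses the sample (n-1) standard deviation and is undefined (None) for
    a zero-mean series.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need >= 2 samples for series statistics")
    median = float(np.median(values))
    mean = float(values.mean())
    if mean == 0:
        return median, mean, None
    if np.ptp(values) == 0:  # exactly constant: avoid spurious rounding in std
        return median, mean, 0.0
    cv = 100.0 * float(values.std(ddof=1)) / mean
    return median, mean, cv


def classify_persistence(
    median: float,
    cv_pct: float | None,
    cv_threshold_pct: float = config.CV_BLOOM_THRESHOLD_PCT,
    median_floor: float = config.MEDIAN_PERSISTENCE_FLOOR,
) -> str:
    """Classify a genome's seasonal dynamics from its abundance summary.

    ``bloom_and_bust`` requires both a large CV and a median below the floor
    (the population is near-absent most of the season); a CV at or below the
    threshold is ``persistent``; a large CV with a high median is
    ``indeterminate``, as is an undefined CV.
    """
    if cv_pct is None:
        return INDETERMINATE
    if cv_pct > cv_threshold_pct and median < median_floor:
        return BLOOM_AND_BUST
    if cv_pct <= cv_threshold_pct:
        return PERSISTENT
    return INDETERMINATE


def summarize_genomes(
    series: dict[str, AbundanceSeries],
    cv_threshold_pct: float = config.CV_BLOOM_THRESHOLD_PCT,
    median_floor: float = config.MEDIAN_PERSISTENCE_FLOOR,
) -> pd.DataFrame:
    """Per-genome median/mean/CV summary table with persistence class."""
    rows = []
    for genome_id in sorted(series):
        median, mean, cv = series[genome_id].stats()
        rows.append(
            {
                "genome_id": genome_id,
                "cov_median": median,
                "cov_mean": mean,
                "cov_cv_pct": float("nan") if cv is None else cv,
                "dynamics": classify_persistence(median, cv, cv_threshold_pct, median_floor),
            }
        )
    return pd.DataFrame(rows).set_index("genome_id")


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def curate_contigs(
    matrix: CoverageMatrix,
    contig_ids: list[str],
    r_min: float = config.CURATION_MIN_R,
) -> pd.DataFrame:
    """Flag contigs whose temporal pattern departs from the genome consensus.

    The reference series is the per-sample median over the genome's contigs.
    Contigs with Pearson r below ``r_min`` against the reference are flagged
    (reason ``low-correlation``); constant contig series are flagged with
    reason ``zero-variance``.  After the first pass the reference is
    recomputed once from the retained contigs and the survivors re-checked
    (single pass, no further iteration).

    Returns a table (contig_id, r, flagged, reason).
    """
    missing = [c for c in contig_ids if c not in matrix.values.index]
    if missing:
        raise ValidationError(f"contigs absent from coverage matrix: {missing}")
    if len(contig_ids) < 3:
        raise ValidationError("need >= 3 contigs to curate")
    block = matrix.values.loc[contig_ids].to_numpy(dtype=float)
    if block.shape[1] < 4:
        raise ValidationError("need >= 4 samples to curate")

    def evaluate(indices: list[int], reference: np.ndarray) -> dict[int, tuple[float | None, bool, str]]:
        result = {}
        for i in indices:
            r = _pearson(block[i], reference)
            if r is None:
                result[i] = (None, True, "zero-variance")
            elif r < r_min:
                result[i] = (r, True, "low-correlation")
            else:
                result[i] = (r, False, "")
        return result

    reference = np.median(block, axis=0)
    if np.ptp(reference) == 0:
        logger.warning("constant reference series; curation is a no-op")
        verdict = {i: (None, False, "constant-reference") for i in range(len(contig_ids))}
    else:
        verdict = evaluate(list(range(len(contig_ids))), reference)
        kept = [i for i, (_, flagged, _) in verdict.items() if not flagged]
        if kept and len(kept) < len(contig_ids) and len(kept) >= 2:
            reference2 = np.median(block[kept], axis=0)
            if np.ptp(reference2) > 0:
                verdict.update(evaluate(kept, reference2))
    rows = [
        {
            "contig_id": contig_ids[i],
            "r": float("nan") if verdict[i][0] is None else verdict[i][0],
            "flagged": verdict[i][1],
            "reason": verdict[i][2],
        }
        for i in range(len(contig_ids))
    ]
    return pd.DataFrame(rows).set_index("contig_id")
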