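"""Functional-family censuses, coding densities, hit filtering and clustering.

A *family class* (glycoside hydrolases, sulfatases, PSCyt domains, ...) is a
rule mapping annotation accessions to family labels.  Census counts are
normalized by each genome's total gene count into *coding densities* (percent
of genes in the class), which makes draft genomes of different completeness
comparable under the assumption that class members are randomly distributed
between the recovered and missing parts of a genome.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import config
from .errors import UndefinedStatisticError, ValidationError
from .io_tables import GeneRecord, HitRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassSpec:
    """How to recognise one functional-family class in annotation accessions.

    Either ``pattern`` (a regex an accession must fully match; the matched
    text is the family label, e.g. ``GH29``) or ``accessions`` (an explicit
    list; each accession is its own family label) must be given.
    """

    name: str
    scheme: str | None = None
    pattern: str | None = None
    accessions: frozenset[str] = frozenset()

    def family_of(self, scheme: str, accession: str) -> str | None:
        if self.scheme is not None and scheme != self.scheme:
            return None
        if self.pattern is not None:
            if re.match(self.pattern, accession):
                return accession
            return None
        if accession in self.accessions:
            return accession
        return None


GH_SPEC = ClassSpec(name="GH", scheme="CAZy", pattern=config.GH_FAMILY_PATTERN)
SULFATASE_SPEC = ClassSpec(name="sulfatase", accessions=config.SULFATASE_ACCESSIONS)
PSCYT_SPEC = ClassSpec(name="PSCyt", accessions=config.PSCYT_ACCESSIONS)

_BUILTIN_SPECS = {s.name: s for s in (GH_SPEC, SULFATASE_SPEC, PSCYT_SPEC)}


def get_class_spec(name: str) -> ClassSpec:
    try:
        return _BUILTIN_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown family class {name!r}; known: {sorted(_BUILTIN_SPECS)}"
        ) from None


@dataclass
class FamilyProfile:
    """Per-genome family counts for one class, with implicit zeros.

    A gene with annotations in two families counts once in each family but
    only once toward the class gene total (chimeric hits are not
    double-counted).
    """

    class_name: str
    counts: dict[str, dict[str, int]]       # genome -> family -> gene count
    gene_totals: dict[str, int]             # genome -> distinct member genes
    families: tuple[str, ...] = ()

    def richness(self, genome_id: str) -> int:
        return len(self.counts.get(genome_id, {}))

    def total(self, genome_id: str) -> int:
        return self.gene_totals.get(genome_id, 0)

    def to_frame(self) -> pd.DataFrame:
        """Dense genomes x families count matrix (implicit zeros filled)."""
        df = pd.DataFrame(
            [
                {fam: self.counts[g].get(fam, 0) for fam in self.families}
                for g in self.counts
            ],
            index=pd.Index(list(self.counts), name="genome_id"),
            columns=list(self.families),
            dtype=int,
        )
        return df


def count_families(
    genes: Iterable[GeneRecord],
    class_spec: ClassSpec | str,
    genome_ids: Iterable[str] | None = None,
) -> FamilyProfile:
    """Census one family class over a gene list.

    ``genome_ids`` fixes cohort membership so genomes with zero members still
    appear (with empty profiles and richness 0).
    """
    spec = get_class_spec(class_spec) if isinstance(class_spec, str) else class_spec
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    if genome_ids is not None:
        for gid in genome_ids:
            counts[gid] = {}
            totals[gid] = 0
    universe: set[str] = set()
    for gene in genes:
        fams = {
            fam
            for scheme, acc in gene.annotations
            if (fam := spec.family_of(scheme, acc)) is not None
        }
        if not fams:
            counts.setdefault(gene.genome_id, {})
            totals.setdefault(gene.genome_id, 0)
            continue
        bucket = counts.setdefault(gene.genome_id, {})
        for fam in fams:
            bucket[fam] = bucket.get(fam, 0) + 1
        totals[gene.genome_id] = totals.get(gene.genome_id, 0) + 1
        universe |= fams
    return FamilyProfile(
        class_name=spec.name,
        counts=counts,
        gene_totals=totals,
        families=tuple(sorted(universe)),
    )


def coding_density(profile_total: int, gene_count: int) -> float:
    """Percent of a genome's genes belonging to a family class."""
    if gene_count <= 0:
        raise ValueError(f"gene_count must be positive, got {gene_count}")
    if profile_total < 0:
        raise ValueError("negative family count")
    return 100.0 * profile_total / gene_count


def density_vector(
    profile: FamilyProfile, gene_counts: Mapping[str, int]
) -> pd.Series:
    """Coding density per genome, as percent of total genes."""
    return pd.Series(
        {g: coding_density(profile.total(g), gene_counts[g]) for g in profile.counts},
        name=f"{profile.class_name}_density_pct",
    )


def filter_gh_hits(hits: Iterable[HitRecord], rule: str) -> list[str]:
    """Apply a hit-acceptance rule; one acceptance per query locus (best E-value).

    ``hmm_default`` keeps E <= 1e-7.  ``gh109`` keeps E <= 1e-6 and query
    coverage >= 50% (the dedicated BLASTP rule for the GH109 family, whose
    HMM domain is not family-specific).
    """
    if rule == "hmm_default":
        accept = lambda h: h.evalue <= config.HMM_EVALUE_CUTOFF  # noqa: E731
    elif rule == "gh109":
        accept = (  # noqa: E731
            lambda h: h.evalue <= config.GH109_EVALUE_CUTOFF
            and h.query_coverage_pct >= config.GH109_MIN_QUERY_COVERAGE
        )
    else:
        raise ValueError(f"unknown hit-filter rule {rule!r}")
    best: dict[str, HitRecord] = {}
    for h in hits:
        if not accept(h):
            continue
        cur = best.get(h.query_locus)
        if cur is None or h.evalue < cur.evalue:
            best[h.query_locus] = h
    return sorted(best)


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value between two vectors.

    Pearson by default (p from the t distribution with n-2 df); Spearman
    available for rank-based robustness.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ClusterResult:
    """Deterministic agglomeration of genome profiles.

    ``merges`` has one row per merge: left and right cluster labels (genome
    ids for leaves, ``node<k>`` for internal nodes), merge height and size.
    """

    leaf_order: list[str]
    merges: pd.DataFrame
    linkage_matrix: np.ndarray
    distance: str
    linkage: str


def cluster_profiles(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterResult:
    """Hierarchically cluster genomes by family-abundance profiles.

    Rows are genomes, columns families.  Ties are broken deterministically by
    sorting genomes lexically before agglomeration.  Correlation distance is
    undefined for all-zero (constant) profiles; use ``bray_curtis`` for those.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("need >= 2 genomes to cluster")
    if distance not in {"correlation", "bray_curtis"}:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in {"average", "complete"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    matrix = matrix.sort_index()
    X = matrix.to_numpy(dtype=float)
    if distance == "correlation":
        if (np.ptp(X, axis=1) == 0).any():
            bad = matrix.index[np.ptp(X, axis=1) == 0].tolist()
            raise UndefinedStatisticError(
                f"constant profile(s) {bad} under correlation distance; "
                "use distance='bray_curtis'"
            )
        dvec = pdist(X, metric="correlation")
    else:
        dvec = pdist(X, metric="braycurtis")
    Z = hierarchy.linkage(dvec, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    genome_ids = list(matrix.index)
    n = len(genome_ids)
    labels = {i: genome_ids[i] for i in range(n)}
    rows = []
    for k, (a, b, h, size) in enumerate(Z):
        labels[n + k] = f"node{k}"
        rows.append(
            {
                "node": f"node{k}",
                "left": labels[int(a)],
                "right": labels[int(b)],
                "height": float(h),
                "size": int(size),
            }
        )
    return ClusterResult(
        leaf_order=[genome_ids[i] for i in leaves],
        merges=pd.DataFrame(rows),
        linkage_matrix=Z,
        distance=distance,
        linkage=linkage,
    )


def top_family_table(profile: FamilyProfile, n_top: int = 10) -> pd.DataFrame:
    """Counts for the ``n_top`` most abundant families plus totals and richness.

    Families are ranked by cohort-wide count (ties by label); the two summary
    columns report each genome's total class gene count and family richness.
    """
    frame = profile.to_frame()
    if frame.empty:
        return frame
    ranked = (
        frame.sum(axis=0).sort_values(ascending=False, kind="stable").index[:n_top]
    )
    out = frame[list(ranked)].copy()
    out[f"total_{profile.class_name}"] = [profile.total(g) for g in out.index]
    out[f"n_{profile.class_name}_families"] = [profile.richness(g) for g in out.index]
    return out


def plot_profile_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Minimal grayscale matrix plot of a family-count table (darker = larger)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(3, 0.3 * matrix.shape[0]))
    )
    ax.imshow(matrix.to_numpy(dtype=float), cmap="Greys", aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
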