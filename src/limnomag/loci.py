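"""Motif scanning and gene-neighborhood locus detection.

Three locus classes are called from annotation tables plus (for PCC) protein
sequences:

* **PCC** (porin-multiheme-cytochrome complex): an outer-membrane porin-like
  gene with a high predicted transmembrane-strand count adjacent to a
  periplasmic c-type cytochrome carrying many CxxCH heme-binding motifs; an
  extracellular multiheme cytochrome in the same neighborhood is recorded as
  optional supporting evidence.  Such complexes are candidate conduits for
  extracellular electron transfer.
* **CUT** (carbohydrate-utilization locus): a TonB-dependent receptor
  clustering with inner-membrane sugar transporters and glycoside
  hydrolases.
* **BMC** (bacterial microcompartment): shell-protein genes clustering with
  L-fucose / L-rhamnose degradation genes.

Neighborhood windows are gene-count based (robust to gene-length variation)
and detection is strand-agnostic and symmetric under reversal of contig gene
order.  Overlapping candidate windows merge into one maximal call per locus
type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import config
from .errors import ValidationError
from .io_tables import GeneRecord
from .profiles import GH_SPEC

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
# X (unknown residue) is tolerated in sequences but never matches C or H.
_VALID_RESIDUES = AMINO_ACIDS | {"X"}


@dataclass(frozen=True, slots=True)
class MotifScan:
    """CxxCH heme-binding-site scan result for one protein."""

    locus_tag: str
    heme_motif_count: int
    positions: tuple[int, ...]  # 1-based index of each motif's first residue


@dataclass(frozen=True, slots=True)
class LocusCall:
    """One detected gene-neighborhood locus."""

    locus_type: str  # PCC | CUT | BMC
    genome_id: str
    contig_id: str
    members: tuple[str, ...]              # locus_tags, contig order
    evidence: tuple[tuple[str, str], ...]  # (role, locus_tag) pairs
    span_bp: int
    gh_surface_fraction: float | None = None

    def evidence_roles(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for role, tag in self.evidence:
            out.setdefault(role, []).append(tag)
        return out


def count_cxxch(sequence: str, locus_tag: str = "", motif: str = "CxxCH") -> MotifScan:
    """Count (possibly overlapping) heme-binding motif windows in a protein.

    The default motif is the canonical c-type cytochrome heme-binding site
    Cys-X-X-Cys-His.  Lowercase input is accepted; ``X`` residues never
    match a constrained position.  An empty sequence scans to count 0.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValidationError(f"{locus_tag or 'sequence'}: non-amino-acid characters {sorted(bad)}")
    pattern = motif.upper()
    k = len(pattern)
    positions = []
    for i in range(len(seq) - k + 1):
        ok = True
        for j, want in enumerate(pattern):
            if want != "X" and seq[i + j] != want:
                ok = False
                break
        if ok:
            positions.append(i + 1)
    return MotifScan(locus_tag=locus_tag, heme_motif_count=len(positions), positions=tuple(positions))


# ---------------------------------------------------------------------------
# neighborhood machinery
# ---------------------------------------------------------------------------


def _by_contig(genes: Iterable[GeneRecord]) -> dict[tuple[str, str], list[GeneRecord]]:
    contigs: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        contigs.setdefault((g.genome_id, g.contig_id), []).append(g)
    for members in contigs.values():
        members.sort(key=lambda g: g.gene_index)
    return contigs


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping (gene-index) intervals into maximal ones."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _minimal_windows(
    roles: Sequence[frozenset[str]],
    required: Sequence[frozenset[str]],
    window: int,
) -> list[tuple[int, int]]:
    """Minimal contiguous index windows (length <= window) satisfying every
    requirement (a requirement is met by any gene whose roles intersect it)."""
    n = len(roles)
    out = []
    for i in range(n):
        have = [False] * len(required)
        for j in range(i, min(n, i + window)):
            for r, req in enumerate(required):
                if not have[r] and roles[j] & req:
                    have[r] = True
            if all(have):
                # left-minimality: gene i must be load-bearing
                if not _satisfies(roles, required, i + 1, j, window):
                    out.append((i, j))
                break
    return out


def _satisfies(
    roles: Sequence[frozenset[str]],
    required: Sequence[frozenset[str]],
    lo: int,
    hi: int,
    window: int,
) -> bool:
    if lo > hi or hi - lo + 1 > window:
        return False
    return all(any(roles[j] & req for j in range(lo, hi + 1)) for req in required)


def _span_bp(members: Sequence[GeneRecord]) -> int:
    return max(g.end for g in members) - min(g.start for g in members) + 1


# ---------------------------------------------------------------------------
# PCC
# ---------------------------------------------------------------------------


def detect_pcc(
    genes: Iterable[GeneRecord],
    sequences: Mapping[str, str],
    min_tm: int = config.PCC_MIN_TM_STRANDS,
    min_hemes: int = config.PCC_MIN_HEMES,
    max_intervening: int = config.PCC_MAX_INTERVENING,
    exact_hemes: bool = False,
) -> list[LocusCall]:
    """Detect porin-multiheme-cytochrome neighborhoods.

    A call needs an outer-membrane gene with ``tm_strand_count >= min_tm``
    and a periplasmic protein with at least (or, with ``exact_hemes``,
    exactly) ``min_hemes`` CxxCH motifs, separated by at most
    ``max_intervening`` genes.  Periplasmic/extracellular candidates lacking
    a protein sequence are skipped with a warning.
    """
    heme_ok = (lambda c: c == min_hemes) if exact_hemes else (lambda c: c >= min_hemes)
    calls: list[LocusCall] = []
    for (genome_id, contig_id), members in _by_contig(genes).items():
        porins = [
            k
            for k, g in enumerate(members)
            if g.localization == "outer_membrane"
            and g.tm_strand_count is not None
            and g.tm_strand_count >= min_tm
        ]
        if not porins:
            continue
        heme_counts: dict[int, int] = {}
        for k, g in enumerate(members):
            if g.localization in {"periplasmic", "extracellular"}:
                seq = sequences.get(g.locus_tag)
                if seq is None:
                    logger.warning(
                        "%s: no protein sequence for candidate %s; skipped",
                        genome_id,
                        g.locus_tag,
                    )
                    continue
                heme_counts[k] = count_cxxch(seq, g.locus_tag).heme_motif_count
        window = max_intervening + 1  # max index distance porin <-> MHC
        intervals = []
        for p in porins:
            mhcs = [
                k
                for k, c in heme_counts.items()
                if members[k].localization == "periplasmic"
                and heme_ok(c)
                and 0 < abs(k - p) <= window
            ]
            if not mhcs:
                continue
            lo = min([p] + mhcs)
            hi = max([p] + mhcs)
            intervals.append((lo, hi))
        for lo, hi in _merge_intervals(intervals):
            # widen to catch extracellular MHC evidence within the window
            elo, ehi = max(0, lo - window), min(len(members) - 1, hi + window)
            evidence: list[tuple[str, str]] = []
            span_members = members[lo : hi + 1]
            for k in range(lo, hi + 1):
                g = members[k]
                if (
                    g.localization == "outer_membrane"
                    and g.tm_strand_count is not None
                    and g.tm_strand_count >= min_tm
                ):
                    evidence.append(("porin", g.locus_tag))
                elif g.localization == "periplasmic" and heme_ok(heme_counts.get(k, 0)):
                    evidence.append(("periplasmic_MHC", g.locus_tag))
            extra = [
                members[k]
                for k in range(elo, ehi + 1)
                if members[k].localization == "extracellular" and heme_ok(heme_counts.get(k, 0))
            ]
            for g in extra:
                evidence.append(("extracellular_MHC", g.locus_tag))
                if g not in span_members:
                    span_members = sorted(span_members + [g], key=lambda x: x.gene_index)
            calls.append(
                LocusCall(
                    locus_type="PCC",
                    genome_id=genome_id,
                    contig_id=contig_id,
                    members=tuple(g.locus_tag for g in span_members),
                    evidence=tuple(evidence),
                    span_bp=_span_bp(span_members),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# CUT / BMC
# ---------------------------------------------------------------------------


def _gene_roles(
    gene: GeneRecord,
    role_accessions: Mapping[str, frozenset[str]],
    with_gh: bool,
) -> frozenset[str]:
    roles = set()
    accs = {a for _, a in gene.annotations}
    for role, wanted in role_accessions.items():
        if accs & wanted:
            roles.add(role)
    if with_gh and any(GH_SPEC.family_of(s, a) for s, a in gene.annotations):
        roles.add("GH")
    return frozenset(roles)


def _extend_over_role_genes(
    lo: int, hi: int, roles: Sequence[frozenset[str]], window: int
) -> tuple[int, int]:
    """Grow a qualifying window over directly adjacent role-bearing genes
    (symmetrically, capped at the window size) so calls are maximal."""
    changed = True
    while changed and hi - lo + 1 < window:
        changed = False
        if lo > 0 and roles[lo - 1] and hi - lo + 2 <= window:
            lo -= 1
            changed = True
        if hi < len(roles) - 1 and roles[hi + 1] and hi - lo + 2 <= window:
            hi += 1
            changed = True
    return lo, hi


def _neighborhood_calls(
    genes: Iterable[GeneRecord],
    locus_type: str,
    role_accessions: Mapping[str, frozenset[str]],
    required: Sequence[frozenset[str]],
    window: int,
    with_gh: bool,
) -> list[LocusCall]:
    calls: list[LocusCall] = []
    for (genome_id, contig_id), members in _by_contig(genes).items():
        roles = [_gene_roles(g, role_accessions, with_gh) for g in members]
        windows = _minimal_windows(roles, required, window)
        extended = [
            _extend_over_role_genes(lo, hi, roles, window) for lo, hi in windows
        ]
        for lo, hi in _merge_intervals(extended):
            span_members = members[lo : hi + 1]
            evidence = []
            gh_tags = []
            for k in range(lo, hi + 1):
                for role in sorted(roles[k]):
                    evidence.append((role, members[k].locus_tag))
                    if role == "GH":
                        gh_tags.append(k)
            gh_surface = None
            if gh_tags:
                surface = sum(
                    members[k].localization in {"extracellular", "outer_membrane"}
                    for k in gh_tags
                )
                gh_surface = surface / len(gh_tags)
            calls.append(
                LocusCall(
                    locus_type=locus_type,
                    genome_id=genome_id,
                    contig_id=contig_id,
                    members=tuple(g.locus_tag for g in span_members),
                    evidence=tuple(evidence),
                    span_bp=_span_bp(span_members),
                    gh_surface_fraction=gh_surface if locus_type == "CUT" else None,
                )
            )
    return calls


def detect_cut(
    genes: Iterable[GeneRecord],
    window: int = config.NEIGHBORHOOD_WINDOW_GENES,
    tbdr_accessions: frozenset[str] = config.TBDR_ACCESSIONS,
    transporter_accessions: frozenset[str] = config.INNER_TRANSPORTER_ACCESSIONS,
) -> list[LocusCall]:
    """Detect carbohydrate-utilization loci: >=1 TonB-dependent receptor,
    >=1 inner-membrane sugar transporter and >=1 GH within a gene window.

    The fraction of member GH genes predicted extracellular or
    outer-membrane is reported per call (``gh_surface_fraction``).
    """
    role_accessions = {
        "TBDR": tbdr_accessions,
        "inner_transporter": transporter_accessions,
    }
    required = [
        frozenset({"TBDR"}),
        frozenset({"inner_transporter"}),
        frozenset({"GH"}),
    ]
    return _neighborhood_calls(genes, "CUT", role_accessions, required, window, with_gh=True)


def detect_bmc(
    genes: Iterable[GeneRecord],
    window: int = config.NEIGHBORHOOD_WINDOW_GENES,
    shell_accessions: frozenset[str] = config.BMC_SHELL_ACCESSIONS,
    fucose_accessions: frozenset[str] = config.FUCOSE_ACCESSIONS,
    rhamnose_accessions: frozenset[str] = config.RHAMNOSE_ACCESSIONS,
) -> list[LocusCall]:
    """Detect bacterial-microcompartment loci: >=1 shell-protein gene and
    >=1 fucose- or rhamnose-degradation gene within a gene window."""
    role_accessions = {
        "shell_protein": shell_accessions,
        "fucose_gene": fucose_accessions,
        "rhamnose_gene": rhamnose_accessions,
    }
    required = [
        frozenset({"shell_protein"}),
        frozenset({"fucose_gene", "rhamnose_gene"}),
    ]
    return _neighborhood_calls(genes, "BMC", role_accessions, required, window, with_gh=False)


def calls_to_rows(calls: Iterable[LocusCall]) -> list[dict]:
    """Flatten calls for TSV serialization (evidence as key=value pairs)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_type": c.locus_type,
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "n_members": len(c.members),
                "span_bp": c.span_bp,
                "members": ",".join(c.members),
                "evidence": ";".join(f"{role}={tag}" for role, tag in c.evidence),
                "gh_surface_fraction": (
                    "" if c.gh_surface_fraction is None else f"{c.gh_surface_fraction:.2f}"
                ),
            }
        )
    return rows
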