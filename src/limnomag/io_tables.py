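"""Readers and writers for the pipeline's tabular, GFF3 and FASTA inputs.

All coordinates are 1-based inclusive (GFF3 convention).  Annotation
accessions are carried verbatim (``pfam00884``, ``GH29``, ``K01443``); the
annotation scheme is inferred from the accession prefix unless given
explicitly as ``scheme:accession``.  Missing transmembrane-strand counts and
localizations stay missing/unknown — they are never imputed.

Writers emit UTF-8, tab-delimited files with a commented header line, and
every table type round-trips (``read(write(x)) == x``).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .pathways import PathwayDef

logger = logging.getLogger(__name__)

LOCALIZATIONS = {
    "cytoplasmic",
    "periplasmic",
    "inner_membrane",
    "outer_membrane",
    "extracellular",
    "unknown",
}

LAKE_GROUPS = ("ME", "TE", "TH")

_SCHEME_PATTERNS = [
    ("KO", re.compile(r"^K\d{5}$")),
    ("COG", re.compile(r"^COG\d+$")),
    ("pfam", re.compile(r"^(pfam|PF)\d+$")),
    ("TIGRfam", re.compile(r"^TIGR\d+$")),
    ("CAZy", re.compile(r"^(GH|GT|PL|CE|CBM|AA)\d+$")),
]


def infer_scheme(accession: str) -> str:
    """Infer the annotation scheme from an accession prefix.

    Accessions outside the five standard schemes (e.g. curated role labels
    such as ``TBDR`` or ``BMC_shell``) map to scheme ``other``.
    """
    for scheme, pat in _SCHEME_PATTERNS:
        if pat.match(accession):
            return scheme
    return "other"


def parse_annotation(token: str) -> tuple[str, str]:
    """Parse one annotation token, honouring an explicit ``scheme:`` override."""
    token = token.strip()
    if not token:
        raise ValidationError("empty annotation accession")
    if ":" in token:
        scheme, accession = token.split(":", 1)
        if not accession:
            raise ValidationError(f"empty accession in annotation token {token!r}")
        return scheme, accession
    return infer_scheme(token), token


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One annotated gene on a contig of a MAG."""

    genome_id: str
    contig_id: str
    locus_tag: str
    start: int
    end: int
    strand: str
    gene_index: int = 0
    annotations: frozenset[tuple[str, str]] = frozenset()
    localization: str = "unknown"
    tm_strand_count: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.locus_tag}: invalid strand {self.strand!r}")
        if self.localization not in LOCALIZATIONS:
            raise ValidationError(
                f"{self.locus_tag}: unknown localization {self.localization!r}"
            )
        if self.tm_strand_count is not None and self.tm_strand_count < 0:
            raise ValidationError(f"{self.locus_tag}: negative TM strand count")
        for _, accession in self.annotations:
            if not accession:
                raise ValidationError(f"{self.locus_tag}: empty accession")

    def accessions(self, scheme: str | None = None) -> set[str]:
        """Accessions carried by this gene, optionally restricted to a scheme."""
        return {a for s, a in self.annotations if scheme is None or s == scheme}


@dataclass(frozen=True, slots=True)
class GenomeRecord:
    """Cohort-level metadata for one MAG (one summary-table row)."""

    genome_id: str
    lake_group: str
    subdivision: str = "unclassified"
    size_bp: int | None = None
    completeness_pct: float | None = None
    contamination_pct: float | None = None
    gc_pct: float | None = None
    coding_pct: float | None = None
    gene_count: int | None = None
    cov_median: float | None = None
    cov_mean: float | None = None
    cov_cv_pct: float | None = None

    def __post_init__(self) -> None:
        if self.completeness_pct is not None and not 0 <= self.completeness_pct <= 100:
            raise ValidationError(
                f"{self.genome_id}: completeness {self.completeness_pct} outside [0, 100]"
            )
        if self.contamination_pct is not None and self.contamination_pct < 0:
            raise ValidationError(f"{self.genome_id}: negative contamination")
        if self.gene_count is not None and self.gene_count < 0:
            raise ValidationError(f"{self.genome_id}: negative gene count")


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One homology-search hit (e.g. BLASTP) for a query locus."""

    query_locus: str
    subject_id: str
    evalue: float
    query_coverage_pct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.evalue) or self.evalue < 0:
            raise ValidationError(f"{self.query_locus}: invalid E-value {self.evalue}")
        if not 0 <= self.query_coverage_pct <= 100:
            raise ValidationError(
                f"{self.query_locus}: coverage {self.query_coverage_pct} outside [0, 100]"
            )


@dataclass
class CoverageMatrix:
    """Dense contig x sample coverage-depth matrix plus sample metadata.

    ``values`` rows are contigs, columns are samples ordered by date within
    lake group.  ``samples`` is indexed by sample_id and carries lake_group,
    date and total_mapped_bases.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative coverage depth")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing}")

    def group_samples(self, lake_group: str) -> list[str]:
        """Sample ids of one lake group in date order."""
        sub = self.samples[self.samples["lake_group"] == lake_group]
        return list(sub.index)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_GENE_COLUMNS = [
    "genome_id",
    "contig_id",
    "locus_tag",
    "start",
    "end",
    "strand",
    "annotations",
    "localization",
    "tm_strand_count",
]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _finalize_genes(records: list[GeneRecord]) -> list[GeneRecord]:
    """Sort by (genome, contig, start), assign gene_index, check invariants."""
    records.sort(key=lambda g: (g.genome_id, g.contig_id, g.start, g.locus_tag))
    seen: set[tuple[str, str]] = set()
    out: list[GeneRecord] = []
    index = 0
    prev_key: tuple[str, str] | None = None
    for rec in records:
        tag_key = (rec.genome_id, rec.locus_tag)
        if tag_key in seen:
            raise ValidationError(f"duplicate locus_tag {rec.locus_tag!r} in {rec.genome_id}")
        seen.add(tag_key)
        contig_key = (rec.genome_id, rec.contig_id)
        index = index + 1 if contig_key == prev_key else 1
        prev_key = contig_key
        out.append(replace(rec, gene_index=index))
    return out


def _normalize_strand(raw: str) -> str:
    return {"+": "+", "-": "-", "−": "-"}.get(raw.strip(), raw.strip())


def read_gene_table(path: str | Path, format: str = "tsv") -> list[GeneRecord]:
    """Read a per-gene annotation table (flat TSV or GFF3 dialect).

    Records come back sorted by (genome, contig, start) with ``gene_index``
    assigned as the 1-based ordinal position along each contig.
    """
    if format == "tsv":
        df = _read_tsv(path, _GENE_COLUMNS[:6])
        records = []
        for row in df.itertuples(index=False):
            ann = getattr(row, "annotations", "")
            tm = getattr(row, "tm_strand_count", "")
            loc = getattr(row, "localization", "") or "unknown"
            records.append(
                GeneRecord(
                    genome_id=row.genome_id,
                    contig_id=row.contig_id,
                    locus_tag=row.locus_tag,
                    start=int(row.start),
                    end=int(row.end),
                    strand=_normalize_strand(row.strand),
                    annotations=frozenset(
                        parse_annotation(tok) for tok in str(ann).split(",") if tok.strip()
                    ),
                    localization=loc,
                    tm_strand_count=int(tm) if str(tm).strip() else None,
                )
            )
        return _finalize_genes(records)
    if format == "gff3":
        return _read_gene_gff3(path)
    raise ValueError(f"unknown gene-table format {format!r}")


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _read_gene_gff3(path: str | Path) -> list[GeneRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: GFF3 line has {len(fields)} fields, expected 9")
            contig, _source, _type, start, end, _score, strand, _phase, attrs = fields
            attr = _parse_gff_attributes(attrs)
            for key in ("genome_id", "locus_tag"):
                if key not in attr:
                    raise FormatError(f"{path}: missing required attribute {key!r}")
            ann_raw = attr.get("annotations", "")
            records.append(
                GeneRecord(
                    genome_id=attr["genome_id"],
                    contig_id=contig,
                    locus_tag=attr["locus_tag"],
                    start=int(start),
                    end=int(end),
                    strand=_normalize_strand(strand),
                    annotations=frozenset(
                        parse_annotation(tok) for tok in ann_raw.split(",") if tok.strip()
                    ),
                    localization=attr.get("localization", "unknown") or "unknown",
                    tm_strand_count=(
                        int(attr["tm_strands"]) if attr.get("tm_strands", "") != "" else None
                    ),
                )
            )
    return _finalize_genes(records)


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes as the flat TSV dialect (round-trips with read_gene_table)."""
    rows = []
    for g in genes:
        rows.append(
            {
                "genome_id": g.genome_id,
                "contig_id": g.contig_id,
                "locus_tag": g.locus_tag,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "annotations": ",".join(
                    f"{s}:{a}" if infer_scheme(a) != s else a
                    for s, a in sorted(g.annotations)
                ),
                "localization": g.localization,
                "tm_strand_count": "" if g.tm_strand_count is None else g.tm_strand_count,
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=_GENE_COLUMNS), path, "per-gene annotation table")


def _write_tsv(df: pd.DataFrame, path: str | Path, comment: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# limnomag: {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome tables
# ---------------------------------------------------------------------------


def _opt_float(value: str) -> float | None:
    return float(value) if str(value).strip() not in {"", "NA"} else None


def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    """Read a cohort summary table (one row per MAG).

    ``lake_group`` is taken from an explicit column when present, otherwise
    inferred from the genome_id prefix (ME*/TE*/TH*).  ``size_mbp`` columns
    are converted to base pairs at this boundary.
    """
    df = _read_tsv(path, ["genome_id"])
    records = []
    for row in df.itertuples(index=False):
        genome_id = row.genome_id
        group = getattr(row, "lake_group", "")
        if not group:
            group = genome_id[:2]
        if group not in LAKE_GROUPS:
            raise ValidationError(f"{genome_id}: cannot infer lake group from {group!r}")
        size_bp = None
        if hasattr(row, "size_bp") and str(row.size_bp).strip():
            size_bp = int(row.size_bp)
        elif hasattr(row, "size_mbp") and str(row.size_mbp).strip():
            size_bp = int(round(float(row.size_mbp) * 1e6))
        gene_count = getattr(row, "gene_count", "")
        records.append(
            GenomeRecord(
                genome_id=genome_id,
                lake_group=group,
                subdivision=getattr(row, "subdivision", "") or "unclassified",
                size_bp=size_bp,
                completeness_pct=_opt_float(getattr(row, "completeness_pct", "")),
                contamination_pct=_opt_float(getattr(row, "contamination_pct", "")),
                gc_pct=_opt_float(getattr(row, "gc_pct", "")),
                coding_pct=_opt_float(getattr(row, "coding_pct", "")),
                gene_count=int(gene_count) if str(gene_count).strip() else None,
                cov_median=_opt_float(getattr(row, "cov_median", "")),
                cov_mean=_opt_float(getattr(row, "cov_mean", "")),
                cov_cv_pct=_opt_float(getattr(row, "cov_cv_pct", "")),
            )
        )
    if not records:
        logger.warning("%s: genome table is empty", path)
    return records


def write_genome_table(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    rows = []
    for g in genomes:
        rows.append(
            {
                "genome_id": g.genome_id,
                "lake_group": g.lake_group,
                "subdivision": g.subdivision,
                "size_bp": "" if g.size_bp is None else g.size_bp,
                "completeness_pct": "" if g.completeness_pct is None else g.completeness_pct,
                "contamination_pct": ""
                if g.contamination_pct is None
                else g.contamination_pct,
                "gc_pct": "" if g.gc_pct is None else g.gc_pct,
                "coding_pct": "" if g.coding_pct is None else g.coding_pct,
                "gene_count": "" if g.gene_count is None else g.gene_count,
                "cov_median": "" if g.cov_median is None else g.cov_median,
                "cov_mean": "" if g.cov_mean is None else g.cov_mean,
                "cov_cv_pct": "" if g.cov_cv_pct is None else g.cov_cv_pct,
            }
        )
    _write_tsv(pd.DataFrame(rows), path, "MAG cohort summary table")


def bundled_table2_path() -> Path:
    """Path of the packaged 19-MAG cohort summary fixture."""
    return Path(__file__).parent / "data" / "table2_mags.tsv"


# ---------------------------------------------------------------------------
# pathway definitions
# ---------------------------------------------------------------------------


def read_pathway_defs(path: str | Path) -> list[PathwayDef]:
    """Read curated pathway definitions.

    Dialect: one row per (pathway, step); ``accessions`` is a comma-separated
    OR-group of isofunctional alternatives; ``signature`` marks signature
    steps with 1/0.  Duplicate (pathway, step) rows are merged into one
    OR-group with a logged warning.
    """
    df = _read_tsv(path, ["pathway_id", "step_id", "accessions", "signature"])
    steps: dict[str, dict[str, set[str]]] = {}
    signatures: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    order: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        pid, sid = row.pathway_id, row.step_id
        names.setdefault(pid, getattr(row, "name", "") or pid)
        group = {tok.strip() for tok in row.accessions.split(",") if tok.strip()}
        if not group:
            raise ValidationError(f"pathway {pid} step {sid}: no accessions")
        bucket = steps.setdefault(pid, {})
        if sid in bucket:
            logger.warning("pathway %s: duplicate step %s merged", pid, sid)
            bucket[sid] |= group
        else:
            bucket[sid] = group
            order.setdefault(pid, []).append(sid)
        if str(row.signature).strip() in {"1", "true", "True"}:
            signatures.setdefault(pid, set()).add(sid)
    defs = []
    for pid, sids in order.items():
        defs.append(
            PathwayDef(
                pathway_id=pid,
                name=names[pid],
                steps=tuple(frozenset(steps[pid][sid]) for sid in sids),
                step_ids=tuple(sids),
                signature_steps=frozenset(signatures.get(pid, set())),
            )
        )
    return defs


def write_pathway_defs(defs: Iterable[PathwayDef], path: str | Path) -> None:
    rows = []
    for d in defs:
        for sid, group in zip(d.step_ids, d.steps):
            rows.append(
                {
                    "pathway_id": d.pathway_id,
                    "name": d.name,
                    "step_id": sid,
                    "accessions": ",".join(sorted(group)),
                    "signature": int(sid in d.signature_steps),
                }
            )
    _write_tsv(pd.DataFrame(rows), path, "pathway definition table")


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a tabular homology-hit file (query, subject, E-value, coverage%)."""
    df = _read_tsv(path, ["query_locus", "subject_id", "evalue", "query_coverage_pct"])
    return [
        HitRecord(
            query_locus=row.query_locus,
            subject_id=row.subject_id,
            evalue=float(row.evalue),
            query_coverage_pct=float(row.query_coverage_pct),
        )
        for row in df.itertuples(index=False)
    ]


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    rows = [
        {
            "query_locus": h.query_locus,
            "subject_id": h.subject_id,
            "evalue": h.evalue,
            "query_coverage_pct": h.query_coverage_pct,
        }
        for h in hits
    ]
    _write_tsv(pd.DataFrame(rows), path, "homology hit table")


# ---------------------------------------------------------------------------
# coverage matrices and contig membership
# ---------------------------------------------------------------------------


def read_coverage_matrix(path: str | Path, meta_path: str | Path) -> CoverageMatrix:
    """Read a wide contig x sample coverage matrix plus sample metadata.

    Samples are reordered by date within lake group.  NA cells become 0 with
    a logged warning (absence of mapped reads is the natural reading).
    """
    raw = pd.read_csv(Path(path), sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(
        Path(meta_path), sep="\t", comment="#", dtype={"sample_id": str}
    ).set_index("sample_id")
    for col in ("lake_group", "date", "total_mapped_bases"):
        if col not in meta.columns:
            raise FormatError(f"{meta_path}: missing required column {col!r}")
    meta["date"] = pd.to_datetime(meta["date"])
    unknown = [c for c in raw.columns if c not in meta.index]
    if unknown:
        raise ValidationError(f"samples absent from metadata: {unknown}")
    if raw.isna().any().any():
        logger.warning("%s: NA coverage cells treated as 0", path)
        raw = raw.fillna(0.0)
    meta = meta.sort_values(["lake_group", "date"])
    ordered = [s for s in meta.index if s in raw.columns]
    return CoverageMatrix(values=raw[ordered].astype(float), samples=meta.loc[ordered])


def write_coverage_matrix(matrix: CoverageMatrix, path: str | Path, meta_path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# limnomag: contig x sample coverage-depth matrix\n")
        matrix.values.to_csv(fh, sep="\t", index_label="contig_id")
    meta = matrix.samples.copy()
    meta["date"] = meta["date"].dt.strftime("%Y-%m-%d")
    with open(meta_path, "w", encoding="utf-8") as fh:
        fh.write("# limnomag: sample metadata\n")
        meta.to_csv(fh, sep="\t", index_label="sample_id")


def read_contig_map(path: str | Path) -> pd.DataFrame:
    """Read contig membership (contig_id, genome_id, length_bp), indexed by contig."""
    df = _read_tsv(path, ["contig_id", "genome_id", "length_bp"])
    out = df.set_index("contig_id")
    out["length_bp"] = out["length_bp"].astype(int)
    if (out["length_bp"] <= 0).any():
        raise ValidationError("non-positive contig length")
    return out


def write_contig_map(contigs: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(contigs.reset_index(), path, "contig membership table")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file as an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
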