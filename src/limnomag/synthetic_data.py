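"""Deterministic MAG-cohort generator with known planted truth.

The generator emulates the statistical structure the analysis assumes for a
three-group lake cohort (8 eutrophic-lake epilimnion "ME" genomes, 3 bog
epilimnion "TE", 8 bog hypolimnion "TH"), namely:

* per-genome annotation tables whose gene recovery follows independent
  Bernoulli dropout at a completeness-dependent retention probability
  (completeness drawn from 51-95%),
* group-contrasted functional-family coding densities (GH density about 4%
  in TH vs about 1% in ME, with group-specific overrepresented families;
  sulfatase and PSCyt densities with their own contrasts, PSCyt opposing
  GH),
* planted pathway content drawn from a built-in catalog with per-group
  presence probabilities,
* planted PCC / CUT / BMC gene neighborhoods (PCC only in TH genomes by
  default, mirroring the observed restriction of porin-MHC clusters to the
  humic-substance-rich bog hypolimnion),
* protein sequences that are random strings with planted CxxCH motifs and
  recorded transmembrane-strand counts (no attempt at realistic folds), and
* per-group coverage time series with persistent (bog) versus bloom-and-bust
  (eutrophic-lake) dynamics, plus optional contaminant contigs with
  independent dynamics.

Everything is a pure function of (config, seed); per-genome substreams are
derived deterministically from the global seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import (
    CoverageMatrix,
    GeneRecord,
    GenomeRecord,
    _finalize_genes,
    write_contig_map,
    write_coverage_matrix,
    write_fasta,
    write_gene_table,
    write_genome_table,
    write_pathway_defs,
)
from .pathways import PathwayDef

# ---------------------------------------------------------------------------
# built-in pathway catalog
# ---------------------------------------------------------------------------


def _pathway(pid: str, name: str, steps: list[tuple[str, list[str]]], signature: list[str]) -> PathwayDef:
    return PathwayDef(
        pathway_id=pid,
        name=name,
        steps=tuple(frozenset(accs) for _, accs in steps),
        step_ids=tuple(sid for sid, _ in steps),
        signature_steps=frozenset(signature),
    )


def default_pathway_catalog() -> list[PathwayDef]:
    """A compact catalog of sugar-degradation and nutrient pathways.

    Accessions are KEGG orthology terms for the canonical enzymes; OR-groups
    model isofunctional alternatives.  The TCA entry deliberately declares no
    signature (its enzymes are shared across pathways), exercising the
    no-signature reporting path.
    """
    return [
        _pathway(
            "glycolysis_EM",
            "Embden-Meyerhof glycolysis",
            [
                ("glk", ["K00844", "K00845"]),
                ("pgi", ["K01810"]),
                ("pfk", ["K00850"]),
                ("fba", ["K01623", "K01624"]),
                ("gap", ["K00134"]),
                ("pyk", ["K00873"]),
            ],
            ["pfk"],
        ),
        _pathway(
            "fucose_deg",
            "L-fucose degradation",
            [
                ("fucI", ["K01818"]),
                ("fucK", ["K00879"]),
                ("fucA", ["K01628"]),
                ("fucO", ["K00048"]),
            ],
            ["fucI", "fucA"],
        ),
        _pathway(
            "rhamnose_deg",
            "L-rhamnose degradation",
            [
                ("rhaA", ["K01813"]),
                ("rhaB", ["K00848"]),
                ("rhaD", ["K01629"]),
            ],
            ["rhaD"],
        ),
        _pathway(
            "glycogen_synth",
            "glycogen biosynthesis",
            [
                ("glgC", ["K00975"]),
                ("glgA", ["K00703"]),
                ("glgB", ["K00700"]),
            ],
            ["glgA"],
        ),
        _pathway(
            "nitrogen_fixation",
            "nitrogen fixation",
            [
                ("nifH", ["K02588"]),
                ("nifD", ["K02586"]),
                ("nifK", ["K02591"]),
            ],
            ["nifH"],
        ),
        _pathway(
            "urease",
            "urea hydrolysis",
            [
                ("ureA", ["K01430"]),
                ("ureB", ["K01429"]),
                ("ureC", ["K01428"]),
            ],
            ["ureC"],
        ),
        _pathway(
            "tca_cycle",
            "tricarboxylic acid cycle (partial marker set)",
            [
                ("gltA", ["K01647"]),
                ("acn", ["K01681", "K01682"]),
                ("icd", ["K00031"]),
                ("sucA", ["K00164"]),
                ("mdh", ["K00024"]),
            ],
            [],
        ),
    ]


# Per-group presence probability of each catalog pathway.
DEFAULT_PATHWAY_PRESENCE: dict[str, dict[str, float]] = {
    "glycolysis_EM": {"ME": 0.95, "TE": 0.95, "TH": 0.95},
    "fucose_deg": {"ME": 0.25, "TE": 0.6, "TH": 0.8},
    "rhamnose_deg": {"ME": 0.25, "TE": 0.6, "TH": 0.7},
    "glycogen_synth": {"ME": 0.8, "TE": 0.8, "TH": 0.8},
    "nitrogen_fixation": {"ME": 0.0, "TE": 0.4, "TH": 0.5},
    "urease": {"ME": 0.1, "TE": 0.5, "TH": 0.5},
    "tca_cycle": {"ME": 0.9, "TE": 0.9, "TH": 0.9},
}

# GH family pools: (family, weight). Group-specific pools overrepresent the
# families observed to dominate each lake type; the shared pool adds breadth.
_GH_SHARED = [
    ("GH1", 2), ("GH3", 3), ("GH5", 2), ("GH9", 1), ("GH10", 1), ("GH16", 2),
    ("GH23", 2), ("GH26", 1), ("GH28", 1), ("GH30", 1), ("GH31", 2), ("GH36", 1),
    ("GH38", 1), ("GH39", 1), ("GH43", 2), ("GH51", 1), ("GH53", 1), ("GH63", 1),
    ("GH65", 1), ("GH74", 1), ("GH88", 1), ("GH92", 1), ("GH97", 1), ("GH105", 1),
    ("GH109", 1), ("GH115", 1), ("GH130", 1),
]
_GH_TH_TOP = [("GH2", 10), ("GH29", 8), ("GH78", 8), ("GH95", 6), ("GH106", 6)]
_GH_ME_TOP = [("GH13", 8), ("GH20", 6), ("GH33", 5), ("GH57", 4), ("GH77", 4)]

GH_FAMILY_POOLS: dict[str, list[tuple[str, float]]] = {
    "ME": _GH_ME_TOP + _GH_SHARED,
    "TE": _GH_TH_TOP + _GH_SHARED,
    "TH": _GH_TH_TOP + _GH_SHARED,
}

PSCYT_POOL = ["PSCyt1", "PSCyt2", "PSCyt3", "PSD1", "PSD2", "PSD3", "PSD4", "PSD5"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# Mildly depleted C/H so spurious CxxCH motifs stay rare in filler proteins.
_AA_WEIGHTS = np.array(
    [8, 1, 5, 6, 4, 7, 2, 6, 6, 9, 2, 4, 5, 4, 5, 7, 5, 7, 1, 3], dtype=float
)
_AA_WEIGHTS /= _AA_WEIGHTS.sum()


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    group_sizes: tuple[tuple[str, int], ...] = (("ME", 8), ("TE", 3), ("TH", 8))
    samples_per_group: tuple[tuple[str, int], ...] = (("ME", 94), ("TE", 45), ("TH", 45))
    genes_per_genome: tuple[int, int] = (1200, 2600)
    completeness_range: tuple[float, float] = (51.0, 95.0)
    apply_dropout: bool = True
    contigs_per_genome: int = 5
    # coding densities, percent of genes
    gh_density_pct: tuple[tuple[str, float], ...] = (("ME", 1.0), ("TE", 2.5), ("TH", 4.0))
    sulfatase_density_pct: tuple[tuple[str, float], ...] = (
        ("ME", 0.5), ("TE", 1.0), ("TH", 1.2),
    )
    pscyt_density_pct: tuple[tuple[str, float], ...] = (
        ("ME", 1.5), ("TE", 1.2), ("TH", 0.3),
    )
    # locus planting probabilities per genome
    pcc_probability: tuple[tuple[str, float], ...] = (("ME", 0.0), ("TE", 0.0), ("TH", 1.0))
    cut_probability: tuple[tuple[str, float], ...] = (("ME", 0.0), ("TE", 0.4), ("TH", 0.15))
    bmc_probability: tuple[tuple[str, float], ...] = (("ME", 0.25), ("TE", 0.5), ("TH", 0.6))
    # coverage dynamics per group
    dynamics_by_group: tuple[tuple[str, str], ...] = (
        ("ME", "bloom"), ("TE", "persistent"), ("TH", "persistent"),
    )
    contaminant_probability: float = 0.3
    persistent_noise_sd: float = 0.4       # lognormal sigma
    bloom_baseline: float = 0.05
    bloom_amplitude_range: tuple[float, float] = (5.0, 25.0)
    bloom_width_days: float = 10.0
    contig_sample_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for _, n in self.group_sizes:
            if n < 0:
                raise ValidationError("negative group size")
        lo, hi = self.completeness_range
        if not (0 < lo <= hi <= 100):
            raise ValidationError("completeness range must lie in (0, 100]")
        if self.genes_per_genome[0] < 50 or self.genes_per_genome[0] > self.genes_per_genome[1]:
            raise ValidationError("invalid genes_per_genome range")
        if self.contigs_per_genome < 1:
            raise ValidationError("need >= 1 contig per genome")
        if not 0 <= self.contaminant_probability <= 1:
            raise ValidationError("contaminant probability outside [0, 1]")

    def group_of(self, key: str, table: tuple[tuple[str, float], ...]) -> float:
        return dict(table)[key]


@dataclass
class PlantedLocus:
    locus_type: str
    genome_id: str
    contig_id: str
    member_tags: tuple[str, ...]
    roles: tuple[tuple[str, str], ...]


@dataclass
class GenomeTruth:
    genome_id: str
    lake_group: str
    retention_p: float
    n_true_genes: int
    pathway_presence: dict[str, bool]
    gh_family_counts: dict[str, int]
    sulfatase_count: int
    pscyt_count: int
    dynamics: str
    dynamics_params: dict[str, float]
    contaminant_contigs: tuple[str, ...] = ()


@dataclass
class SyntheticTruth:
    seed: int
    config: CohortConfig
    genomes: dict[str, GenomeTruth]
    loci: list[PlantedLocus]
    abundance: dict[str, np.ndarray]  # planted per-sample genome abundance


@dataclass
class SyntheticCohort:
    """Everything a downstream analysis run needs, plus the planted truth."""

    genes: list[GeneRecord]
    genomes: list[GenomeRecord]
    proteins: dict[str, str]
    pathway_defs: list[PathwayDef]
    coverage: CoverageMatrix
    contig_map: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the cohort in exactly the formats the io_tables readers take."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "genomes": outdir / "genomes.tsv",
            "proteins": outdir / "proteins.faa",
            "pathways": outdir / "pathways.tsv",
            "coverage": outdir / "coverage.tsv",
            "coverage_meta": outdir / "samples.tsv",
            "contigs": outdir / "contigs.tsv",
        }
        write_gene_table(self.genes, paths["genes"])
        write_genome_table(self.genomes, paths["genomes"])
        write_fasta(self.proteins, paths["proteins"])
        write_pathway_defs(self.pathway_defs, paths["pathways"])
        write_coverage_matrix(self.coverage, paths["coverage"], paths["coverage_meta"])
        write_contig_map(self.contig_map, paths["contigs"])
        return paths


# ---------------------------------------------------------------------------
# low-level generators
# ---------------------------------------------------------------------------


def apply_completeness_dropout(
    genes: list, retention_p: float, rng: np.random.Generator
) -> list:
    """Keep each gene independently with probability ``retention_p``.

    This is the generative counterpart of the density-normalization
    assumption that class members are randomly distributed between the
    recovered and missing parts of a genome.
    """
    if not 0 < retention_p <= 1:
        raise ValidationError(f"retention probability {retention_p} outside (0, 1]")
    if retention_p == 1.0:
        return list(genes)
    keep = rng.random(len(genes)) < retention_p
    return [g for g, k in zip(genes, keep) if k]


def simulate_coverage(
    dynamics: str,
    dates: np.ndarray,
    rng: np.random.Generator,
    baseline: float = 3.0,
    noise_sd: float = 0.4,
    amplitude: float = 15.0,
    peak_day: float | None = None,
    width_days: float = 10.0,
) -> np.ndarray:
    """Simulate one genome's abundance series over ordinal sampling days.

    ``persistent``: baseline x lognormal noise.  ``bloom``: a low baseline
    plus a Gaussian-shaped peak in time, with noise.  Output is non-negative.
    """
    days = np.asarray(dates, dtype=float)
    if dynamics == "persistent":
        series = baseline * np.exp(rng.normal(0.0, noise_sd, size=days.size))
    elif dynamics == "bloom":
        if peak_day is None:
            peak_day = float(rng.uniform(days.min(), days.max()))
        peak = amplitude * np.exp(-0.5 * ((days - peak_day) / width_days) ** 2)
        series = (baseline + peak) * np.exp(rng.normal(0.0, noise_sd, size=days.size))
    else:
        raise ValidationError(f"unknown dynamics class {dynamics!r}")
    return np.maximum(series, 0.0)


_AA_BYTES = np.frombuffer("ACDEFGHIKLMNPQRSTVWY".encode(), dtype="S1")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_AA_BYTES), size=length, p=_AA_WEIGHTS)
    return _AA_BYTES[idx].tobytes().decode()


def _mhc_protein(rng: np.random.Generator, n_hemes: int, length: int = 300) -> str:
    """Random protein with exactly ``n_hemes`` planted CxxCH motifs."""
    body = list(_random_protein(rng, length).replace("C", "A").replace("H", "Q"))
    slots = np.sort(rng.choice(np.arange(0, length - 5, 7), size=n_hemes, replace=False))
    for s in slots:
        body[s : s + 5] = list("C") + list(_random_protein(rng, 2).replace("C", "A").replace("H", "Q"))[:2] + ["C", "H"]
    return "".join(body)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _weighted_choice(rng: np.random.Generator, pool: list[tuple[str, float]], size: int) -> list[str]:
    labels = [label for label, _ in pool]
    weights = np.array([w for _, w in pool], dtype=float)
    weights /= weights.sum()
    return list(rng.choice(labels, size=size, p=weights))


@dataclass
class _DraftGene:
    """Pre-layout gene payload (annotations and predicted features only)."""

    annotations: frozenset[tuple[str, str]]
    localization: str = "cytoplasmic"
    tm_strand_count: int | None = None
    protein: str | None = None
    locus_role: tuple[str, str] | None = None  # (locus_key, role)


def _scheme_of(accession: str) -> str:
    from .io_tables import infer_scheme

    return infer_scheme(accession)


def _ann(*accessions: str) -> frozenset[tuple[str, str]]:
    return frozenset((_scheme_of(a), a) for a in accessions)


_LOCALIZATION_POOL = np.array(
    ["cytoplasmic", "inner_membrane", "periplasmic", "outer_membrane", "extracellular", "unknown"]
)
_LOCALIZATION_P = np.array([0.70, 0.10, 0.08, 0.05, 0.04, 0.03])


def _genome_truth_and_genes(
    genome_id: str,
    group: str,
    cfg: CohortConfig,
    catalog: list[PathwayDef],
    rng: np.random.Generator,
) -> tuple[GenomeTruth, list[_DraftGene], list[tuple[str, list[_DraftGene]]]]:
    """Draw one genome's true gene content.

    Returns loose genes plus locus blocks (kept contiguous at layout time).
    """
    n_genes = int(rng.integers(cfg.genes_per_genome[0], cfg.genes_per_genome[1] + 1))

    pathway_presence = {
        pw.pathway_id: bool(
            rng.random() < DEFAULT_PATHWAY_PRESENCE.get(pw.pathway_id, {}).get(group, 0.5)
        )
        for pw in catalog
    }

    loose: list[_DraftGene] = []
    # pathway genes: one gene per step, one accession drawn from the OR-group
    for pw in catalog:
        if not pathway_presence[pw.pathway_id]:
            continue
        for group_accs in pw.steps:
            acc = sorted(group_accs)[int(rng.integers(len(group_accs)))]
            loose.append(_DraftGene(annotations=_ann(acc)))

    # family-class genes at the group's coding density
    gh_n = int(round(cfg.group_of(group, cfg.gh_density_pct) / 100.0 * n_genes))
    gh_families = _weighted_choice(rng, GH_FAMILY_POOLS[group], gh_n)
    gh_counts: dict[str, int] = {}
    for fam in gh_families:
        gh_counts[fam] = gh_counts.get(fam, 0) + 1
        loose.append(_DraftGene(annotations=_ann(fam)))
    sulf_n = int(round(cfg.group_of(group, cfg.sulfatase_density_pct) / 100.0 * n_genes))
    for _ in range(sulf_n):
        loose.append(_DraftGene(annotations=_ann("pfam00884")))
    pscyt_n = int(round(cfg.group_of(group, cfg.pscyt_density_pct) / 100.0 * n_genes))
    for acc in rng.choice(PSCYT_POOL, size=pscyt_n):
        loose.append(_DraftGene(annotations=_ann(str(acc))))

    # locus blocks
    blocks: list[tuple[str, list[_DraftGene]]] = []
    if rng.random() < cfg.group_of(group, cfg.pcc_probability):
        n_hemes = int(rng.integers(8, 11))
        block = [
            _DraftGene(
                annotations=_ann("porin_MHC_porin"),
                localization="outer_membrane",
                tm_strand_count=int(rng.integers(20, 31)),
            ),
            _DraftGene(
                annotations=_ann("cytochrome_c"),
                localization="periplasmic",
                protein=_mhc_protein(rng, n_hemes),
            ),
        ]
        if rng.random() < 0.6:
            block.append(
                _DraftGene(
                    annotations=_ann("cytochrome_c"),
                    localization="extracellular",
                    protein=_mhc_protein(rng, int(rng.integers(8, 11))),
                )
            )
        roles = ["porin", "periplasmic_MHC"] + (
            ["extracellular_MHC"] if len(block) == 3 else []
        )
        for g, role in zip(block, roles):
            g.locus_role = ("PCC", role)
        blocks.append(("PCC", block))

    if rng.random() < cfg.group_of(group, cfg.cut_probability):
        gh_fams = _weighted_choice(rng, GH_FAMILY_POOLS[group], 2)
        block = [
            _DraftGene(annotations=_ann("TBDR"), localization="outer_membrane"),
            _DraftGene(annotations=_ann("inner_sugar_transporter"), localization="inner_membrane"),
            _DraftGene(annotations=_ann(gh_fams[0]), localization="extracellular"),
            _DraftGene(annotations=_ann(gh_fams[1]), localization="outer_membrane"),
        ]
        roles = ["TBDR", "inner_transporter", "GH", "GH"]
        for g, role in zip(block, roles):
            g.locus_role = ("CUT", role)
        for fam in gh_fams:
            gh_counts[fam] = gh_counts.get(fam, 0) + 1
        blocks.append(("CUT", block))

    # BMC loci reuse accessions of a genuinely present sugar pathway so the
    # planted pathway truth stays exact in the no-dropout limit
    bmc_source = None
    if pathway_presence["fucose_deg"]:
        bmc_source = ("fucose_deg", ["K01818", "K01628"], "fucose_gene")
    elif pathway_presence["rhamnose_deg"]:
        bmc_source = ("rhamnose_deg", ["K01813", "K01629"], "rhamnose_gene")
    if bmc_source is not None and rng.random() < cfg.group_of(group, cfg.bmc_probability):
        _, accs, role = bmc_source
        block = [
            _DraftGene(annotations=_ann("BMC_shell")),
            _DraftGene(annotations=_ann(accs[0])),
            _DraftGene(annotations=_ann(accs[1])),
        ]
        roles = ["shell_protein", role, role]
        for g, r in zip(block, roles):
            g.locus_role = ("BMC", r)
        blocks.append(("BMC", block))

    # filler genes to reach the target gene count
    n_planted = len(loose) + sum(len(b) for _, b in blocks)
    n_filler = max(0, n_genes - n_planted)
    locs = rng.choice(_LOCALIZATION_POOL, size=n_filler, p=_LOCALIZATION_P)
    for loc in locs:
        tm = int(rng.integers(8, 15)) if loc == "outer_membrane" and rng.random() < 0.3 else None
        ann = _ann(f"K9{int(rng.integers(0, 500)):04d}") if rng.random() < 0.3 else frozenset()
        loose.append(_DraftGene(annotations=ann, localization=str(loc), tm_strand_count=tm))

    lo, hi = cfg.completeness_range
    retention = float(rng.uniform(lo, hi)) / 100.0 if cfg.apply_dropout else 1.0
    truth = GenomeTruth(
        genome_id=genome_id,
        lake_group=group,
        retention_p=retention,
        n_true_genes=n_genes,
        pathway_presence=pathway_presence,
        gh_family_counts=gh_counts,
        sulfatase_count=sulf_n,
        pscyt_count=pscyt_n,
        dynamics=dict(cfg.dynamics_by_group)[group],
        dynamics_params={},
    )
    return truth, loose, blocks


def _layout_genome(
    genome_id: str,
    loose: list[_DraftGene],
    blocks: list[tuple[str, list[_DraftGene]]],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[_DraftGene, GeneRecord]], list[PlantedLocus], dict[str, int]]:
    """Place genes on contigs with 1-based coordinates; loci stay contiguous."""
    rng.shuffle(loose)
    n_contigs = cfg.contigs_per_genome
    per = max(1, len(loose) // n_contigs)
    contigs: list[list[_DraftGene]] = [
        loose[i * per : (i + 1) * per] if i < n_contigs - 1 else loose[(n_contigs - 1) * per :]
        for i in range(n_contigs)
    ]
    planted: list[PlantedLocus] = []
    block_positions: list[tuple[int, int, str, list[_DraftGene]]] = []
    for locus_type, block in blocks:
        ci = int(rng.integers(n_contigs))
        pos = int(rng.integers(len(contigs[ci]) + 1))
        contigs[ci][pos:pos] = block
        block_positions.append((ci, pos, locus_type, block))

    out: list[tuple[_DraftGene, GeneRecord]] = []
    tag_of: dict[int, str] = {}
    counter = 0
    contig_len: dict[str, int] = {}
    for ci, members in enumerate(contigs):
        contig_id = f"{genome_id}_c{ci + 1}"
        pos = 1
        for g in members:
            counter += 1
            tag = f"{genome_id}_{counter:05d}"
            tag_of[id(g)] = tag
            length = int(rng.integers(100, 800)) * 3
            rec = GeneRecord(
                genome_id=genome_id,
                contig_id=contig_id,
                locus_tag=tag,
                start=pos,
                end=pos + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                annotations=g.annotations,
                localization=g.localization,
                tm_strand_count=g.tm_strand_count,
            )
            out.append((g, rec))
            pos = rec.end + 1 + int(rng.integers(20, 200))
        contig_len[contig_id] = pos + 500
    for ci, _pos, locus_type, block in block_positions:
        contig_id = f"{genome_id}_c{ci + 1}"
        planted.append(
            PlantedLocus(
                locus_type=locus_type,
                genome_id=genome_id,
                contig_id=contig_id,
                member_tags=tuple(tag_of[id(g)] for g in block),
                roles=tuple((g.locus_role[1], tag_of[id(g)]) for g in block),
            )
        )
    return out, planted, contig_len


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 7
) -> SyntheticCohort:
    """Generate a full synthetic MAG cohort with planted truth.

    Fully deterministic given (config, seed): per-genome substreams are
    spawned from the root generator in a fixed order.
    """
    cfg = config or CohortConfig()
    root = np.random.default_rng(seed)
    catalog = default_pathway_catalog()

    genome_ids = [
        f"{group}{i + 1:04d}"
        for group, n in cfg.group_sizes
        for i in range(n)
    ]
    groups = {gid: gid[:2] for gid in genome_ids}

    truths: dict[str, GenomeTruth] = {}
    all_genes: list[GeneRecord] = []
    proteins: dict[str, str] = {}
    planted_loci: list[PlantedLocus] = []
    contig_rows: list[dict] = []
    genome_records: list[GenomeRecord] = []

    # sample frames per group (weekly sampling seasons)
    sample_meta_rows = []
    sample_days: dict[str, np.ndarray] = {}
    for group, n_samples in cfg.samples_per_group:
        days = np.arange(n_samples) * 7.0
        sample_days[group] = days
        dates = pd.Timestamp("2008-05-01") + pd.to_timedelta(days, unit="D")
        for i, date in enumerate(dates):
            sample_meta_rows.append(
                {
                    "sample_id": f"{group}_s{i + 1:03d}",
                    "lake_group": group,
                    "date": date,
                    "total_mapped_bases": float(root.lognormal(mean=np.log(1e9), sigma=0.3)),
                }
            )
    samples = pd.DataFrame(sample_meta_rows).set_index("sample_id")
    samples = samples.sort_values(["lake_group", "date"])
    ref_total = float(samples["total_mapped_bases"].median())

    coverage_rows: dict[str, np.ndarray] = {}
    abundance: dict[str, np.ndarray] = {}

    substreams = root.spawn(len(genome_ids))
    for gid, rng in zip(genome_ids, substreams):
        group = groups[gid]
        truth, loose, blocks = _genome_truth_and_genes(gid, group, cfg, catalog, rng)
        laid, planted, contig_len = _layout_genome(gid, loose, blocks, cfg, rng)
        planted_loci.extend(planted)

        # dropout
        keep_mask = (
            rng.random(len(laid)) < truth.retention_p
            if truth.retention_p < 1.0
            else np.ones(len(laid), dtype=bool)
        )
        retained = [pair for pair, k in zip(laid, keep_mask) if k]
        for g, rec in retained:
            all_genes.append(rec)
            if g.protein is not None:
                proteins[rec.locus_tag] = g.protein
            elif rec.localization in {"periplasmic", "extracellular", "outer_membrane"}:
                proteins[rec.locus_tag] = _random_protein(rng, int(rng.integers(120, 400)))

        # contigs and coverage
        dynamics = truth.dynamics
        days = sample_days[group]
        if dynamics == "persistent":
            baseline = float(rng.uniform(1.5, 8.0))
            params = {"baseline": baseline, "noise_sd": cfg.persistent_noise_sd}
            series = simulate_coverage(
                "persistent", days, rng, baseline=baseline, noise_sd=cfg.persistent_noise_sd
            )
        else:
            amplitude = float(rng.uniform(*cfg.bloom_amplitude_range))
            peak_day = float(rng.uniform(days.min(), days.max()))
            params = {
                "baseline": cfg.bloom_baseline,
                "amplitude": amplitude,
                "peak_day": peak_day,
                "width_days": cfg.bloom_width_days,
                "noise_sd": cfg.persistent_noise_sd,
            }
            series = simulate_coverage(
                "bloom",
                days,
                rng,
                baseline=cfg.bloom_baseline,
                noise_sd=cfg.persistent_noise_sd,
                amplitude=amplitude,
                peak_day=peak_day,
                width_days=cfg.bloom_width_days,
            )
        truth.dynamics_params = params
        abundance[gid] = series

        group_sample_ids = list(samples[samples["lake_group"] == group].index)
        group_totals = samples.loc[group_sample_ids, "total_mapped_bases"].to_numpy()
        n_cols = len(samples)
        col_index = {s: j for j, s in enumerate(samples.index)}
        contaminants = []
        for contig_id, length in contig_len.items():
            factor = float(rng.lognormal(0.0, 0.1))
            noise = np.exp(rng.normal(0.0, cfg.contig_sample_noise_sd, size=len(group_sample_ids)))
            raw = series * factor * noise * group_totals / ref_total
            row = np.zeros(n_cols)
            for s, v in zip(group_sample_ids, raw):
                row[col_index[s]] = v
            coverage_rows[contig_id] = row
            contig_rows.append({"contig_id": contig_id, "genome_id": gid, "length_bp": length})
        if rng.random() < cfg.contaminant_probability:
            contig_id = f"{gid}_cX"
            indep = simulate_coverage(
                "persistent", days, rng, baseline=float(rng.uniform(0.5, 5.0)), noise_sd=0.8
            )
            raw = indep * group_totals / ref_total
            row = np.zeros(n_cols)
            for s, v in zip(group_sample_ids, raw):
                row[col_index[s]] = v
            coverage_rows[contig_id] = row
            contig_rows.append({"contig_id": contig_id, "genome_id": gid, "length_bp": 8000})
            contaminants.append(contig_id)
        truth.contaminant_contigs = tuple(contaminants)
        truths[gid] = truth

        n_retained = int(keep_mask.sum())
        genome_records.append(
            GenomeRecord(
                genome_id=gid,
                lake_group=group,
                subdivision="synthetic",
                size_bp=int(sum(contig_len.values())),
                completeness_pct=round(100.0 * truth.retention_p, 1),
                contamination_pct=0.0,
                gc_pct=55.0,
                coding_pct=90.0,
                gene_count=n_retained,
            )
        )

    all_genes = _finalize_genes(all_genes)
    values = pd.DataFrame.from_dict(coverage_rows, orient="index", columns=list(samples.index))
    values = values.sort_index()
    coverage = CoverageMatrix(values=values, samples=samples)
    contig_map = pd.DataFrame(contig_rows).set_index("contig_id").sort_index()

    return SyntheticCohort(
        genes=all_genes,
        genomes=genome_records,
        proteins=proteins,
        pathway_defs=catalog,
        coverage=coverage,
        contig_map=contig_map,
        truth=SyntheticTruth(
            seed=seed, config=cfg, genomes=truths, loci=planted_loci, abundance=abundance
        ),
    )
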