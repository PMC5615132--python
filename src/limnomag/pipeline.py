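"""End-to-end orchestration over one MAG cohort.

``run_all`` loads the cohort inputs, runs every analysis stage and writes a
report bundle:

* ``completeness_matrix.tsv``  -- genome x pathway tri-state completeness
* ``densities.tsv``            -- GH / sulfatase / PSCyt coding densities
* ``top_families.tsv``         -- top GH family counts, totals and richness
* ``locus_calls.tsv``          -- PCC / CUT / BMC neighborhood calls
* ``abundance_summary.tsv``    -- per-genome median/mean/CV and dynamics
* ``run_metadata.yaml``        -- every applied parameter value and the seed

Execution is single-process and fully deterministic: outputs are a pure
function of inputs + config.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import config as defaults
from . import io_tables, loci, pathways, profiles, timeseries
from .errors import LimnomagError, ValidationError

logger = logging.getLogger(__name__)

_PATH_KEYS = ("genes", "genomes", "pathways", "proteins", "coverage", "coverage_meta", "contigs")

_DEFAULT_PARAMS = {
    "pcc_min_tm": defaults.PCC_MIN_TM_STRANDS,
    "pcc_min_hemes": defaults.PCC_MIN_HEMES,
    "pcc_max_intervening": defaults.PCC_MAX_INTERVENING,
    "neighborhood_window": defaults.NEIGHBORHOOD_WINDOW_GENES,
    "cv_bloom_threshold_pct": defaults.CV_BLOOM_THRESHOLD_PCT,
    "median_persistence_floor": defaults.MEDIAN_PERSISTENCE_FLOOR,
    "curation_min_r": defaults.CURATION_MIN_R,
    "cluster_distance": "correlation",
    "cluster_linkage": "average",
    "top_families": 10,
}


class StageError(LimnomagError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration (paths, parameters, output dir, seed)."""

    inputs: dict[str, str]
    outdir: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {"inputs", "outdir", "seed", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            inputs=raw.get("inputs", {}),
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}),
        )

    def validate(self) -> None:
        missing_keys = [k for k in _PATH_KEYS if k not in self.inputs]
        if missing_keys:
            raise ValidationError(f"missing input paths: {missing_keys}")
        unknown = set(self.inputs) - set(_PATH_KEYS)
        if unknown:
            raise ValidationError(f"unknown input keys: {sorted(unknown)}")
        for key in _PATH_KEYS:
            if not Path(self.inputs[key]).exists():
                raise ValidationError(f"input path for {key!r} does not exist: {self.inputs[key]}")
        unknown_params = set(self.params) - set(_DEFAULT_PARAMS)
        if unknown_params:
            raise ValidationError(f"unknown parameters: {sorted(unknown_params)}")

    def param(self, key: str):
        return self.params.get(key, _DEFAULT_PARAMS[key])


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except LimnomagError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, exc) from exc
        return run
    return wrap


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage; returns the paths of the emitted report bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = io_tables.read_gene_table(cfg.inputs["genes"])
    genomes = io_tables.read_genome_table(cfg.inputs["genomes"])
    pathway_defs = io_tables.read_pathway_defs(cfg.inputs["pathways"])
    proteins = io_tables.read_fasta(cfg.inputs["proteins"])
    coverage = io_tables.read_coverage_matrix(cfg.inputs["coverage"], cfg.inputs["coverage_meta"])
    contig_map = io_tables.read_contig_map(cfg.inputs["contigs"])

    genome_ids = [g.genome_id for g in genomes]
    gene_counts = {gid: 0 for gid in genome_ids}
    for g in genes:
        gene_counts[g.genome_id] = gene_counts.get(g.genome_id, 0) + 1

    out: dict[str, Path] = {}

    @_stage("pathway_completeness")
    def stage_pathways():
        cohort = pathways.cohort_from_genes(genes, genome_ids)
        matrix = pathways.cohort_completeness_matrix(cohort, pathway_defs)
        path = outdir / "completeness_matrix.tsv"
        io_tables._write_tsv(matrix.reset_index(), path, "pathway completeness matrix (1 / 0 / (0) / fraction)")
        return path

    @_stage("coding_densities")
    def stage_densities():
        rows = {}
        for spec in (profiles.GH_SPEC, profiles.SULFATASE_SPEC, profiles.PSCYT_SPEC):
            profile = profiles.count_families(genes, spec, genome_ids)
            rows[f"{spec.name}_density_pct"] = profiles.density_vector(profile, gene_counts)
        df = pd.DataFrame(rows)
        df.index.name = "genome_id"
        path = outdir / "densities.tsv"
        io_tables._write_tsv(df.reset_index(), path, "family-class coding densities (% of genes)")
        return path

    @_stage("top_families")
    def stage_top_families():
        profile = profiles.count_families(genes, profiles.GH_SPEC, genome_ids)
        table = profiles.top_family_table(profile, n_top=cfg.param("top_families"))
        path = outdir / "top_families.tsv"
        io_tables._write_tsv(table.reset_index(), path, "top family counts with totals and richness")
        return path

    @_stage("locus_detection")
    def stage_loci():
        calls = []
        calls += loci.detect_pcc(
            genes,
            proteins,
            min_tm=cfg.param("pcc_min_tm"),
            min_hemes=cfg.param("pcc_min_hemes"),
            max_intervening=cfg.param("pcc_max_intervening"),
        )
        calls += loci.detect_cut(genes, window=cfg.param("neighborhood_window"))
        calls += loci.detect_bmc(genes, window=cfg.param("neighborhood_window"))
        path = outdir / "locus_calls.tsv"
        io_tables._write_tsv(
            pd.DataFrame(
                loci.calls_to_rows(calls),
                columns=[
                    "locus_type", "genome_id", "contig_id", "n_members",
                    "span_bp", "members", "evidence", "gh_surface_fraction",
                ],
            ),
            path,
            "PCC/CUT/BMC locus calls",
        )
        return path

    @_stage("abundance_summary")
    def stage_abundance():
        groups = {g.genome_id: g.lake_group for g in genomes}
        series = timeseries.normalize_coverage(coverage, contig_map, genome_groups=groups)
        summary = timeseries.summarize_genomes(
            series,
            cv_threshold_pct=cfg.param("cv_bloom_threshold_pct"),
            median_floor=cfg.param("median_persistence_floor"),
        )
        path = outdir / "abundance_summary.tsv"
        io_tables._write_tsv(
            summary.round(3).reset_index(), path, "normalized coverage summary (median/mean/CV%)"
        )
        return path

    out["completeness_matrix"] = stage_pathways()
    out["densities"] = stage_densities()
    out["top_families"] = stage_top_families()
    out["locus_calls"] = stage_loci()
    out["abundance_summary"] = stage_abundance()

    metadata = {
        "seed": cfg.seed,
        "inputs": {k: str(v) for k, v in cfg.inputs.items()},
        "parameters": {k: cfg.param(k) for k in _DEFAULT_PARAMS},
        "n_genomes": len(genomes),
        "n_genes": len(genes),
        "assumed_provenance": "coverage matrix from read mapping at >=95% identity (upstream)",
    }
    meta_path = outdir / "run_metadata.yaml"
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)
    out["metadata"] = meta_path
    return out
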