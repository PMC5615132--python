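"""Pathway-completeness scoring with a signature-gene fallback rule.

Draft genomes binned from metagenomes are incomplete, so a missing enzyme
may reflect genome incompleteness rather than true pathway absence.
Completeness of a pathway in a genome is therefore estimated as the fraction
of its enzymatic steps with at least one recovered gene, and pathway-specific
*signature* enzymes arbitrate whether a partially recovered pathway is
reported at all:

* signature recovered in the genome -> report the fraction;
* signature absent in the genome but present in at least one-third of the
  cohort (ceiling; 7 of 19) -> still report the fraction, crediting genome
  incompleteness;
* signature absent here and in more than two-thirds of the cohort -> the
  pathway is likely absent, reported as ``(0)``;
* no step recovered at all -> 0.

A step is an OR-group of isofunctional alternative accessions and counts
once toward the step total however many alternatives are present.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .io_tables import GeneRecord

logger = logging.getLogger(__name__)

STATE_FRACTION = "fraction"
STATE_ZERO = "zero"
STATE_LIKELY_ABSENT = "likely_absent"


@dataclass(frozen=True, slots=True)
class PathwayDef:
    """Enzyme requirements for one pathway.

    ``steps`` is an ordered tuple of OR-groups (frozensets of accessions);
    ``signature_steps`` names the step_ids whose enzymes are specific to this
    pathway (may be empty, in which case the prevalence fallback never
    applies and the pathway cannot be called likely-absent).
    """

    pathway_id: str
    name: str
    steps: tuple[frozenset[str], ...]
    step_ids: tuple[str, ...]
    signature_steps: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValidationError(f"pathway {self.pathway_id}: zero steps")
        if len(self.step_ids) != len(self.steps):
            raise ValidationError(f"pathway {self.pathway_id}: step id/group mismatch")
        unknown = self.signature_steps - set(self.step_ids)
        if unknown:
            raise ValidationError(
                f"pathway {self.pathway_id}: signature steps {sorted(unknown)} not in steps"
            )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def signature_groups(self) -> list[frozenset[str]]:
        return [g for sid, g in zip(self.step_ids, self.steps) if sid in self.signature_steps]


@dataclass(frozen=True, slots=True)
class CompletenessCall:
    """Tri-state pathway completeness for one genome x pathway cell."""

    genome_id: str
    pathway_id: str
    state: str
    completeness: float | None
    recovered_steps: int
    prevalence_support: int
    no_signature: bool = False

    def cell(self) -> str:
        """Serialize per the tri-state reporting convention."""
        if self.state == STATE_ZERO:
            return "0"
        if self.state == STATE_LIKELY_ABSENT:
            return "(0)"
        if self.completeness == 1.0:
            return "1"
        return f"{self.completeness:.2f}"


def prevalence_threshold(n_genomes: int) -> int:
    """Smallest integer >= one-third of the cohort size (19 -> 7)."""
    if n_genomes < 1:
        raise ValueError(f"cohort size must be >= 1, got {n_genomes}")
    return math.ceil(n_genomes / 3)


def genome_accessions(genes: Iterable["GeneRecord"]) -> set[str]:
    """All annotation accessions present in a genome's gene list."""
    out: set[str] = set()
    for g in genes:
        out |= {a for _, a in g.annotations}
    return out


def step_recovered(accessions: set[str], or_group: frozenset[str]) -> bool:
    """True iff any accession of the OR-group occurs in the genome."""
    return not accessions.isdisjoint(or_group)


def signature_present(accessions: set[str], pathway: PathwayDef) -> bool:
    """True iff any signature step of the pathway is recovered (any-semantics)."""
    return any(step_recovered(accessions, g) for g in pathway.signature_groups())


def signature_prevalence(
    cohort: Mapping[str, set[str]], pathway: PathwayDef
) -> int:
    """Number of cohort genomes in which the pathway's signature is present."""
    return sum(signature_present(acc, pathway) for acc in cohort.values())


def score_pathway(
    genome_id: str,
    accessions: set[str],
    pathway: PathwayDef,
    cohort_signature_prevalence: int,
    n_genomes: int,
) -> CompletenessCall:
    """Score one pathway in one genome under the tri-state convention.

    ``cohort_signature_prevalence`` must have been computed over the same
    cohort that ``n_genomes`` sizes.
    """
    recovered = sum(step_recovered(accessions, g) for g in pathway.steps)
    fraction = recovered / pathway.n_steps
    if not pathway.signature_steps:
        # No declared signature: cannot be called likely-absent.
        if recovered == 0:
            state, completeness = STATE_ZERO, None
        else:
            state, completeness = STATE_FRACTION, fraction
            logger.debug(
                "pathway %s has no signature; fraction for %s flagged no-signature",
                pathway.pathway_id,
                genome_id,
            )
        return CompletenessCall(
            genome_id, pathway.pathway_id, state, completeness, recovered,
            cohort_signature_prevalence, no_signature=True,
        )
    if recovered == 0:
        return CompletenessCall(
            genome_id, pathway.pathway_id, STATE_ZERO, None, 0,
            cohort_signature_prevalence,
        )
    if signature_present(accessions, pathway) or (
        cohort_signature_prevalence >= prevalence_threshold(n_genomes)
    ):
        return CompletenessCall(
            genome_id, pathway.pathway_id, STATE_FRACTION, fraction, recovered,
            cohort_signature_prevalence,
        )
    return CompletenessCall(
        genome_id, pathway.pathway_id, STATE_LIKELY_ABSENT, None, recovered,
        cohort_signature_prevalence,
    )


def cohort_completeness(
    cohort: Mapping[str, set[str]],
    pathways: Sequence[PathwayDef],
) -> dict[tuple[str, str], CompletenessCall]:
    """Score every genome x pathway cell; prevalence computed once per pathway."""
    genome_ids = list(cohort)
    if len(set(genome_ids)) != len(genome_ids):
        raise ValidationError("duplicate genome_id in cohort")
    n = len(genome_ids)
    calls: dict[tuple[str, str], CompletenessCall] = {}
    for pw in pathways:
        if not pw.signature_steps:
            logger.warning(
                "pathway %s declares no signature: its calls are flagged "
                "no-signature and can never be reported likely-absent",
                pw.pathway_id,
            )
        prevalence = signature_prevalence(cohort, pw)
        for gid in genome_ids:
            calls[(gid, pw.pathway_id)] = score_pathway(
                gid, cohort[gid], pw, prevalence, n
            )
    return calls


def cohort_completeness_matrix(
    cohort: Mapping[str, set[str]],
    pathways: Sequence[PathwayDef],
) -> pd.DataFrame:
    """Genome x pathway table of serialized tri-state cells ("1"/"0"/"(0)"/fraction)."""
    if not cohort or not pathways:
        raise ValidationError("cohort and pathway list must be non-empty")
    calls = cohort_completeness(cohort, pathways)
    data = {
        pw.pathway_id: [calls[(gid, pw.pathway_id)].cell() for gid in cohort]
        for pw in pathways
    }
    return pd.DataFrame(data, index=pd.Index(list(cohort), name="genome_id"))


def cohort_from_genes(
    genes: Iterable["GeneRecord"],
    genome_ids: Iterable[str] | None = None,
) -> dict[str, set[str]]:
    """Group a flat gene list into per-genome accession sets.

    ``genome_ids`` fixes the cohort membership and order (genomes with no
    annotated genes then appear with empty sets); otherwise insertion order.
    """
    cohort: dict[str, set[str]] = {}
    if genome_ids is not None:
        for gid in genome_ids:
            cohort[gid] = set()
    for g in genes:
        cohort.setdefault(g.genome_id, set()).update(a for _, a in g.annotations)
    return cohort
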