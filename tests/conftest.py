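import pytest
from hypothesis import settings

from limnomag.io_tables import GeneRecord
from limnomag.synthetic_data import CohortConfig, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (dropout on), shared across tests."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-dropout cohort: recovered content equals planted truth exactly."""
    return generate_cohort(CohortConfig(apply_dropout=False), seed=11)


def make_contig(genome_id, contig_id, specs):
    """Build an ordered gene list for one contig from compact spec dicts.

    Each spec may carry: ann (list of accession strings), loc, tm.
    """
    from limnomag.io_tables import infer_scheme

    genes = []
    pos = 1
    for i, spec in enumerate(specs):
        ann = frozenset((infer_scheme(a), a) for a in spec.get("ann", []))
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=contig_id,
                locus_tag=f"{genome_id}_{contig_id}_{i + 1:03d}",
                start=pos,
                end=pos + 899,
                strand="+",
                gene_index=i + 1,
                annotations=ann,
                localization=spec.get("loc", "cytoplasmic"),
                tm_strand_count=spec.get("tm"),
            )
        )
        pos += 1000
    return genes
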