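import numpy as np
import pytest

from limnomag.errors import ValidationError
from limnomag.io_tables import GeneRecord
from limnomag.loci import (
    LocusCall,
    count_cxxch,
    detect_bmc,
    detect_cut,
    detect_pcc,
)

from _oracles import oracle_cxxch
from conftest import make_contig


class TestCxxchScan:
    def test_single_planted_motif(self):
        scan = count_cxxch("MCAACHAA")
        assert scan.heme_motif_count == 1
        assert scan.positions == (2,)

    def test_two_motifs(self):
        scan = count_cxxch("CGGCHCGGCH")
        assert scan.heme_motif_count == 2

    def test_no_motif_and_empty_sequence(self):
        assert count_cxxch("MAAAA").heme_motif_count == 0
        assert count_cxxch("").heme_motif_count == 0

    def test_x_never_matches_constrained_positions(self):
        assert count_cxxch("XGGCH").heme_motif_count == 0
        assert count_cxxch("CXXCH").heme_motif_count == 1  # X on free positions is fine

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValidationError):
            count_cxxch("MC1ACH")

    def test_overlapping_motifs_counted(self):
        # CxxCH starting at 1 and at 4: C A A C H ... construct CAACAACH? check brute force agrees
        seq = "CAACHACHCAACH"
        assert count_cxxch(seq).positions == tuple(oracle_cxxch(seq))

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(3)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWYX"))
        for _ in range(300):
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(0, 120))))
            assert count_cxxch(seq).positions == tuple(oracle_cxxch(seq))


PORIN = {"loc": "outer_membrane", "tm": 24}
MHC9 = {"loc": "periplasmic", "seq_hemes": 9}
FILLER = {}


def _contig_with_seqs(specs, genome="TH01", contig="c1"):
    genes = make_contig(genome, contig, specs)
    seqs = {}
    for gene, spec in zip(genes, specs):
        hemes = spec.get("seq_hemes")
        if hemes is not None:
            seqs[gene.locus_tag] = "AAG" * 10 + "CAACH" * hemes + "GGA" * 10
        elif spec.get("loc") in {"periplasmic", "extracellular"}:
            seqs[gene.locus_tag] = "MAAAAKLLG" * 8
    return genes, seqs


class TestDetectPcc:
    def test_adjacent_porin_and_periplasmic_mhc_called(self):
        genes, seqs = _contig_with_seqs([FILLER, PORIN, MHC9, FILLER])
        calls = detect_pcc(genes, seqs)
        assert len(calls) == 1
        roles = calls[0].evidence_roles()
        assert len(roles["porin"]) == 1 and len(roles["periplasmic_MHC"]) == 1

    def test_low_tm_porin_not_called(self):
        genes, seqs = _contig_with_seqs([{"loc": "outer_membrane", "tm": 12}, MHC9])
        assert detect_pcc(genes, seqs) == []

    def test_separation_beyond_window_not_called(self):
        genes, seqs = _contig_with_seqs([PORIN] + [FILLER] * 5 + [MHC9])
        assert detect_pcc(genes, seqs) == []

    def test_seven_hemes_below_default_minimum(self):
        genes, seqs = _contig_with_seqs([PORIN, {"loc": "periplasmic", "seq_hemes": 7}])
        assert detect_pcc(genes, seqs) == []

    def test_exact_heme_mode(self):
        genes, seqs = _contig_with_seqs([PORIN, MHC9])
        assert detect_pcc(genes, seqs, exact_hemes=True) == []
        genes, seqs = _contig_with_seqs([PORIN, {"loc": "periplasmic", "seq_hemes": 8}])
        assert len(detect_pcc(genes, seqs, exact_hemes=True)) == 1

    def test_missing_sequence_skips_candidate_with_warning(self, caplog):
        genes, seqs = _contig_with_seqs([PORIN, MHC9])
        seqs.pop(genes[1].locus_tag)
        with caplog.at_level("WARNING"):
            assert detect_pcc(genes, seqs) == []
        assert "no protein sequence" in caplog.text

    def test_extracellular_mhc_recorded_as_optional_evidence(self):
        genes, seqs = _contig_with_seqs(
            [PORIN, MHC9, {"loc": "extracellular", "seq_hemes": 8}]
        )
        (call,) = detect_pcc(genes, seqs)
        assert "extracellular_MHC" in call.evidence_roles()


CUT_BLOCK = [
    {"ann": ["TBDR"], "loc": "outer_membrane"},
    {"ann": ["inner_sugar_transporter"], "loc": "inner_membrane"},
    {"ann": ["GH29"], "loc": "extracellular"},
    {"ann": ["GH2"], "loc": "outer_membrane"},
]


class TestDetectCut:
    def test_planted_window_called_with_four_evidence_roles(self):
        genes = make_contig("G1", "c1", [FILLER] + CUT_BLOCK + [FILLER])
        (call,) = detect_cut(genes)
        assert len(call.evidence) == 4
        assert call.gh_surface_fraction == 1.0

    def test_tbdr_alone_not_called(self):
        genes = make_contig("G1", "c1", [{"ann": ["TBDR"]}, FILLER])
        assert detect_cut(genes) == []

    def test_two_disjoint_windows_give_two_calls(self):
        specs = CUT_BLOCK + [FILLER] * 20 + CUT_BLOCK
        genes = make_contig("G1", "c1", specs)
        calls = detect_cut(genes)
        assert len(calls) == 2
        members = [set(c.members) for c in calls]
        assert members[0].isdisjoint(members[1])

    def test_cytoplasmic_gh_lowers_surface_fraction(self):
        block = [
            {"ann": ["TBDR"]},
            {"ann": ["inner_sugar_transporter"]},
            {"ann": ["GH29"], "loc": "cytoplasmic"},
            {"ann": ["GH2"], "loc": "extracellular"},
        ]
        (call,) = detect_cut(make_contig("G1", "c1", block))
        assert call.gh_surface_fraction == 0.5


class TestDetectBmc:
    def test_shell_plus_fucose_called(self):
        genes = make_contig("G1", "c1", [{"ann": ["BMC_shell"]}, {"ann": ["K01628"]}])
        (call,) = detect_bmc(genes)
        assert "fucose_gene" in call.evidence_roles()

    def test_shell_plus_rhamnose_called(self):
        genes = make_contig("G1", "c1", [{"ann": ["BMC_shell"]}, {"ann": ["K01629"]}])
        (call,) = detect_bmc(genes)
        assert "rhamnose_gene" in call.evidence_roles()

    @pytest.mark.parametrize("ann", [["BMC_shell"], ["K01628", "K01629"]])
    def test_one_side_alone_not_called(self, ann):
        genes = make_contig("G1", "c1", [{"ann": [a]} for a in ann])
        assert detect_bmc(genes) == []


def _reverse_contig(genes):
    """Reverse gene order on the contig, reassigning coordinates/indices."""
    out = []
    n = len(genes)
    for i, g in enumerate(reversed(genes)):
        out.append(
            GeneRecord(
                genome_id=g.genome_id,
                contig_id=g.contig_id,
                locus_tag=g.locus_tag,
                start=1 + i * 1000,
                end=900 + i * 1000,
                strand="-" if g.strand == "+" else "+",
                gene_index=i + 1,
                annotations=g.annotations,
                localization=g.localization,
                tm_strand_count=g.tm_strand_count,
            )
        )
    return out


class TestReversalInvariance:
    def test_calls_invariant_under_reversing_gene_order(self):
        specs = [FILLER, PORIN, MHC9, FILLER] + CUT_BLOCK + [
            {"ann": ["BMC_shell"]},
            {"ann": ["K01628"]},
        ]
        genes, seqs = _contig_with_seqs(specs)
        fwd = detect_pcc(genes, seqs) + detect_cut(genes) + detect_bmc(genes)
        rev_genes = _reverse_contig(genes)
        rev = detect_pcc(rev_genes, seqs) + detect_cut(rev_genes) + detect_bmc(rev_genes)
        assert {(c.locus_type, frozenset(c.members)) for c in fwd} == {
            (c.locus_type, frozenset(c.members)) for c in rev
        }


class TestSyntheticRecovery:
    def test_perfect_precision_and_recall_without_dropout(self, clean_cohort):
        calls = (
            detect_pcc(clean_cohort.genes, clean_cohort.proteins)
            + detect_cut(clean_cohort.genes)
            + detect_bmc(clean_cohort.genes)
        )
        planted = {(l.locus_type, l.genome_id, l.contig_id) for l in clean_cohort.truth.loci}
        called = {(c.locus_type, c.genome_id, c.contig_id) for c in calls}
        assert called == planted

    def test_pcc_restricted_to_hypolimnion_group(self, clean_cohort):
        pcc = [l for l in clean_cohort.truth.loci if l.locus_type == "PCC"]
        assert pcc and all(l.genome_id.startswith("TH") for l in pcc)

    def test_recall_degrades_monotonically_with_dropout(self):
        """Planted-locus recall can only fall as gene retention drops."""
        from limnomag.synthetic_data import CohortConfig, generate_cohort

        recalls = []
        for completeness in (100.0, 70.0, 40.0):
            cfg = CohortConfig(
                completeness_range=(completeness, completeness),
                apply_dropout=completeness < 100.0,
                contaminant_probability=0.0,
            )
            cohort = generate_cohort(cfg, seed=5)
            planted = {
                (l.locus_type, l.genome_id, l.contig_id) for l in cohort.truth.loci
            }
            if not planted:
                continue
            calls = (
                detect_pcc(cohort.genes, cohort.proteins)
                + detect_cut(cohort.genes)
                + detect_bmc(cohort.genes)
            )
            called = {(c.locus_type, c.genome_id, c.contig_id) for c in calls}
            recalls.append(len(called & planted) / len(planted))
        assert recalls == sorted(recalls, reverse=True)
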