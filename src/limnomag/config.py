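"""Default accession lists and thresholds used by the census and locus detectors.

Every list here is a configurable default: real analyses should review them
against their annotation source.  Role labels mix real database accessions
with curated placeholders so that both annotated tables and the synthetic
cohorts exercise the same code paths.
"""

from __future__ import annotations

# -- functional-family class definitions (profiles module) -------------------

# Glycoside hydrolases: CAZy family labels GH1, GH2, ...
GH_FAMILY_PATTERN = r"^GH\d+$"

# Sulfatase family (arylsulfatase domain).
SULFATASE_ACCESSIONS = frozenset({"pfam00884"})

# "Planctomycete-specific" cytochrome c and companion domains (PSCyt1-3,
# PSD1-5).  These domains have no standard public accessions, so the labels
# themselves act as accessions; override with project-specific ids as needed.
PSCYT_ACCESSIONS = frozenset(
    {"PSCyt1", "PSCyt2", "PSCyt3", "PSD1", "PSD2", "PSD3", "PSD4", "PSD5"}
)

# -- locus-detection role lists (loci module) --------------------------------

# TonB-dependent receptors (outer-membrane active carbohydrate/siderophore
# transporters).
TBDR_ACCESSIONS = frozenset({"TBDR", "COG1629", "pfam00593"})

# Inner-membrane sugar transporter components.
INNER_TRANSPORTER_ACCESSIONS = frozenset(
    {"inner_sugar_transporter", "COG1175", "COG0395", "COG1129", "COG2211"}
)

# Bacterial microcompartment shell proteins.
BMC_SHELL_ACCESSIONS = frozenset({"BMC_shell", "pfam00936", "pfam03319"})

# L-fucose degradation enzymes (isomerase, kinase, aldolase, lactaldehyde
# reductase).
FUCOSE_ACCESSIONS = frozenset({"K01818", "K00879", "K01628", "K00048", "fucose_deg"})

# L-rhamnose degradation enzymes (isomerase, kinase, aldolase).
RHAMNOSE_ACCESSIONS = frozenset({"K01813", "K00848", "K01629", "rhamnose_deg"})

# -- locus-detection thresholds ----------------------------------------------

# Porin candidates: predicted beta-barrel transmembrane strand count.
PCC_MIN_TM_STRANDS = 20
# Multiheme cytochrome c candidates: CxxCH heme-binding motif count.
PCC_MIN_HEMES = 8
# Porin and periplasmic MHC must be within this many intervening genes.
PCC_MAX_INTERVENING = 2
# CUT and BMC neighborhoods: maximal window, in genes.
NEIGHBORHOOD_WINDOW_GENES = 15

# -- homology-hit filtering ---------------------------------------------------

HMM_EVALUE_CUTOFF = 1e-7          # dbCAN-style HMM hits
GH109_EVALUE_CUTOFF = 1e-6        # BLASTP rule for GH109
GH109_MIN_QUERY_COVERAGE = 50.0   # percent

# -- time series --------------------------------------------------------------

CV_BLOOM_THRESHOLD_PCT = 150.0    # above: candidate bloom-and-bust
MEDIAN_PERSISTENCE_FLOOR = 1.0    # normalized depth below which blooms bottom out
CURATION_MIN_R = 0.6              # contig-vs-reference Pearson r

# -- alignment / composition ---------------------------------------------------

MAX_GAP_COLUMN_FRACTION = 0.30    # columns gappier than this are trimmed
TNF_WINDOW_BP = 5000
TNF_MIN_WINDOW_BP = 1000
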