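# Methods

This note documents the models, rules and numerical choices behind
`limnomag`, and what the synthetic cohorts do and do not establish about
real data.

## Pathway-completeness model

A pathway is an ordered list of enzymatic *steps*; each step is an OR-group
of isofunctional accessions (KO terms primarily, with COG/pfam/TIGRfam used
where no KO exists) and counts once toward the step total regardless of how
many alternatives are present. Completeness in genome *g* is
`r/|steps|` with `r` the number of steps having at least one recovered
accession.

Because draft genomes are incomplete, a missing enzyme is ambiguous.
Pathway-specific *signature* enzymes arbitrate:

* signature recovered in *g* → report the fraction;
* signature absent in *g* but present in ≥ ⌈N/3⌉ of the N cohort genomes →
  still report the fraction (the gap is credited to genome incompleteness);
* signature absent in *g* and in more than two-thirds of the cohort →
  likely absent, serialized `"(0)"`;
* no step recovered → `"0"`.

Choices made where the rule was underdetermined:

* **One-third is a ceiling.** ⌈19/3⌉ = 7 matches the worked 19-genome case;
  ceiling also gives the sane 1-of-1 behaviour for tiny cohorts.
* **Multiple signature steps use any-semantics**: the signature counts as
  present if any signature step is recovered. This is the permissive
  reading, consistent with the rule's purpose of rescuing incomplete
  genomes.
* **Pathways without a declared signature** (shared-enzyme pathways such as
  the TCA marker set) can never be called likely-absent; they report a
  fraction or zero and every call carries a `no_signature` flag, with one
  warning per pathway at scoring time.
* **Fractions are emitted exactly** (two decimals), not binned.

Prevalence is computed once per pathway over the cohort, so scoring is a
pure function of (cohort, definitions) and deleting a genome can only lower
prevalence support.

## Family censuses and coding density

A family class maps accessions to family labels: GH families by the CAZy
`GH<number>` pattern, sulfatases by pfam00884, PSCyt by a configurable label
list (these domains have no standard public accessions; the labels
PSCyt1–3 / PSD1–5 act as accessions by default). A gene annotated to two
families counts once per family but once toward the class total, so
chimeric hits are not double-counted.

Coding density is `100 × class_total / gene_count`, with `gene_count` the
*recovered* gene count of the genome. Density is the comparable statistic
across genomes of different completeness under the assumption that class
members are randomly distributed between the recovered and missing parts of
a genome — exactly the dropout model the synthetic generator implements, and
the reason the subsampling-invariance test holds.

Homology-hit filters: HMM-style hits accepted at E ≤ 1e−7; the GH109 BLASTP
rule at E ≤ 1e−6 and query coverage ≥ 50% (the family's HMM domain is not
family-specific, hence the dedicated rule); one acceptance per query locus,
keeping the best E-value.

Correlation diagnostics default to Pearson (p two-sided from the t
distribution, n−2 df), with Spearman exposed since the choice is not always
stated in practice. Profile clustering defaults to correlation distance
with average linkage; Bray–Curtis and complete linkage are available, and
correlation distance refuses constant profiles rather than silently
producing NaNs. Genomes are sorted lexically before agglomeration so tie
handling is deterministic; the run's distance/linkage are recorded in the
result object.

## Locus detection

Neighborhood windows are counted in genes, not base pairs, making detection
robust to gene-length variation; all detectors are strand-agnostic and
symmetric under reversing contig gene order, and never cross contig ends.

* **PCC**: an outer-membrane gene with `tm_strand_count ≥ 20` within at most
  2 intervening genes of a periplasmic protein with ≥ 8 CxxCH motifs.
  The heme-binding motif is fixed to the canonical c-type site C-x-x-C-H
  (configurable); `X` residues never satisfy a constrained position. The
  heme threshold is ≥ 8 by default with an exact-8 mode, since "eight
  conserved sites" could be read either way. An extracellular protein with
  ≥ 8 motifs in the same window is recorded as optional
  `extracellular_MHC` evidence. Candidates lacking a protein sequence are
  skipped with a warning rather than guessed.
* **CUT**: a ≤ 15-gene window containing ≥ 1 TonB-dependent receptor, ≥ 1
  inner-membrane sugar transporter and ≥ 1 GH. Each call reports the
  fraction of member GH genes predicted extracellular or outer-membrane.
* **BMC**: a ≤ 15-gene window containing ≥ 1 shell-protein gene and ≥ 1
  fucose- or rhamnose-degradation gene.

Minimal qualifying windows are found first, extended symmetrically over
directly adjacent role-bearing genes (capped at the window size), and
overlapping windows merge into one maximal call per locus type. Role
accession lists live in `limnomag.config` and mix real database accessions
with curated labels; they are defaults to be reviewed per annotation
source.

## Coverage normalization and dynamics

The normalization contract has two steps: (1) each sample's depths are
multiplied by `reference_depth / total_mapped_bases`, the reference being
the median per-sample total (library-size correction; samples with zero
mapped bases are excluded with a warning); (2) a genome's abundance is the
length-weighted mean of its contigs' scaled depths, which makes the value
invariant under splitting a contig. Coverage matrices are assumed to come
from read mapping at ≥ 95% identity upstream; this provenance is recorded in
run metadata, not enforced. Statistics are computed within a genome's own
lake group's samples, since depths are only comparable within one
co-assembly's sample set.

Summaries are median, mean and CV% (sample standard deviation over mean;
ddof = 1). An exactly constant series reports CV = 0 exactly rather than
inheriting rounding error from the standard deviation; a zero-mean series
has undefined CV and classifies as indeterminate. Classification:
bloom-and-bust requires CV > 150% *and* median < 1.0 (near-absent most of
the season); CV ≤ 150% is persistent; a high CV with a high median is
indeterminate. The threshold and floor are configuration, chosen to
separate the two regimes the generator produces (persistent series at
lognormal noise σ = 0.4 have CV ≈ 40%; bloom series with a ≥ 5× peak over a
0.05 baseline have CV well above 200% and median ≈ baseline).

Contig curation compares each contig's series to the per-sample median over
the genome's contigs (Pearson r), flags r < 0.6 (`low-correlation`) or
undefined r (`zero-variance`), then recomputes the reference once from the
survivors and re-checks them — a single pass, kept non-iterative so results
are auditable. The 0.6 default is a declared package choice; no printed
value exists for "did not correlate well".

## Composition and alignment utilities

TNF windows tile contigs in 5,000-bp steps; a trailing fragment shorter
than 1,000 bp merges into the previous window, and contigs shorter than
1,000 bp yield no vector (the usable-window floor is a package decision).
Counts are over all overlapping 4-mers within a window (4-mers containing N
skipped), L1-normalized; the default is the raw 256-dimension vector, with
a canonical reverse-complement-merged 136-dimension mode for
strand-insensitive work. Downstream embedding (e.g. self-organizing maps)
is out of scope; vectors are emitted for any embedding or clustering.

Alignment trimming removes columns whose gap fraction strictly exceeds 30%
(a column at exactly 30% is retained), preserving row order; the operation
is idempotent.

## Synthetic cohorts: what they emulate, and what they do not

Defaults mirror the reference study conditions: 19 genomes in groups of
8 ME / 3 TE / 8 TH; 94/45/45 weekly samples per group; completeness drawn
uniformly from 51–95% and applied as independent per-gene retention; GH
coding density ~1% (ME), ~2.5% (TE), ~4% (TH) with group-specific
overrepresented families (GH2/GH29/GH78/GH95/GH106 in the bog,
GH13/GH20/GH33/GH57/GH77 in the eutrophic lake); sulfatase densities higher
in the bog and PSCyt densities opposing GH; PCC loci planted only in TH
genomes; CUT loci concentrated in TE/TH; BMC loci planted in genomes whose
fucose/rhamnose pathway is genuinely present (about 7 of 19 in
expectation); ME genomes get bloom dynamics, bog genomes persistent
dynamics; contaminant contigs with independent dynamics planted at
probability 0.3 per genome. Proteins are random strings with planted CxxCH
motifs and recorded transmembrane-strand counts — composition only, no
realistic folds. One integer seed drives everything through per-genome
substreams, so cohorts are byte-reproducible.

Passing recovery tests on these cohorts shows the *rules* are implemented
correctly and are statistically identifiable under the stated generative
model. It does not validate upstream annotation quality, localization or
TM-strand prediction accuracy, non-random gene loss (e.g. whole-contig
dropout), inter-genome contamination, or real protein sequence statistics —
on real data those error sources dominate.

## Problem sizes and determinism

Default synthetic cohorts carry 1,200–2,600 true genes per genome on 5
contigs. Recovery-rate checks use 100 seeds (density contrast), 100
simulations (contaminant flagging, dynamics classification) or 3 cohorts
(zero-dropout locus recovery); oracle-equivalence checks enumerate small
presence-pattern spaces exhaustively and sample 500 random cohorts at the
5-step/6-genome corner. All stochastic tests are seeded; hypothesis
property tests run derandomized.
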