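# Methods

This note documents the models behind each stage, the synthetic-data
generator that the test suite measures them against, and the numerical and
design choices that were genuinely open.

## tRNA reference and quantification

Mature tRNA genes are highly redundant: many loci carry byte-identical
mature sequences, and no read can be attributed to an individual locus.
The reference collapses identical sequences (after uppercasing and U→T
normalisation, so RNA- and DNA-alphabet inputs behave identically) into a
single record; the representative name is the lexicographically smallest
member, a deterministic convention with no biological content. Identical
sequences carrying conflicting anticodon annotations indicate malformed
input and abort.

Read assignment is exact substring matching against the collapsed set,
keeping reads of at least 15 nt (shorter truncated reverse-transcription
products are uninformative). A read contained in *k* records contributes
1/*k* to each. This is a deliberate simplification of an aligner +
mapping-quality filter + EM-based quantifier stack: at desk scale, exact
matching with fractional multi-mapping allocation captures the same
accounting while staying fully transparent. Aggregation to anticodon and
amino-acid levels sums counts and preserves column totals exactly;
mitochondrial features keep an `MT-` prefix so compartments never merge.

## Differential expression

Size factors follow the median-of-ratios construction: only features with
positive counts in every sample enter; each sample's factor is the median of
its ratios to per-feature geometric means. Counts are modelled as NB2
(Var = μ + αμ²) with a log link and log size-factor offsets; the Wald
statistic for the condition coefficient is referred to the standard normal
and BH-adjusted.

Dispersion is estimated by the method of moments, α = (s² − m)/m² on
normalised counts, with variances pooled **within** conditions (so true
signal does not inflate the estimate), then averaged **across** features
into a single common dispersion (unfloored per-feature values are averaged
so negative sampling noise cancels; the final value is floored at 1e-8).
This is the classic common-dispersion design. The rationale: with three
replicates per group a per-feature moment estimator has ~4 degrees of
freedom and is so noisy that a normal-reference Wald test becomes badly
anticonservative (empirically ~0.12 type-I error at nominal 0.05), while
plugging in the pooled estimate restores calibration (~0.05) at full power.
The cost is that feature-specific dispersion differences are ignored — no
empirical-Bayes shrinkage toward a mean-dispersion trend is attempted, which
is the main numerical divergence from modern DE tools. On data with strongly
heterogeneous dispersions the test will be liberal for the noisiest features.

Features with all-zero counts are reported with missing statistics. A
feature that is all-zero in one condition only still gets an effect size,
computed from 0.5-pseudocount normalised means; its p-value is reported only
if the GLM converges.

## Footprint QC

Transcript coordinates are 0-based, half-open everywhere; loaders validate
CDS bounds and frame-divisibility. The per-length P-site offset is the mode
of `cds_start − five_prime_pos` over reads that cover the first CDS
nucleotide with their 5′ end strictly upstream; ties break toward the
smaller offset, and lengths with fewer than `min_reads_per_length` (default
50) qualifying reads inherit the global modal offset. This start-overlap
modal rule is a simplified form of the offset estimation used by riboWaltz,
without the 3′-extremity correction step. It is identifiable because
initiating ribosomes pile up on the start codon; a library without an
initiation peak would make all distances `offset − 3i` equally common.

Regions use half-open comparisons (P-site exactly at `cds_start` is CDS,
frame 0; exactly at `cds_end` is 3′UTR). Frames are labelled 0/1/2 with
frame 0 the in-frame signal (conventions that label frames 1–3 call the
same signal "frame 1").

## Codon occupancy

Only in-frame CDS P-sites have an unambiguous codon; out-of-frame reads are
excluded from codon calling. The P-site codon index is
`(psite − cds_start)/3`; A-site is the next codon (possibly the stop codon,
for terminating ribosomes), E-site the previous; indices outside the CDS are
dropped. Occupancy is frequency-normalised, occ_c = N_c / F_c, where F_c
counts occurrences of codon c in the CDSs of transcripts that received at
least one P-site, and reported as percentages summing to 100. Stop codons
are reported at codon level but excluded (and the rest renormalised) at
amino-acid level.

Tissue contrasts are computed two ways. Welch's unequal-variance *t*-test
compares per-replicate occupancy values codon by codon; when both groups
have zero variance the p-value is 1 for equal means and 0 otherwise, a
documented edge convention. Relative enrichment is the mean over all
replicate pairs (i, j) of the **quotient** logCPM_A,i / logCPM_B,j with
logCPM = log2(CPM + 1); the quotient (rather than a difference of logs)
matches a reference line at 1 for equal enrichment. With 3 + 3 replicates
each codon gets 9 ratios and their mean and standard error. Codons whose
denominator logCPM is not positive are excluded and flagged. The +1
pseudocount keeps ratios defined at zero counts.

## Translational regulation

The interaction model fits, per gene, counts from both assays jointly:
`log μ = β0 + β1·assay + β2·condition + β3·assay×condition`, with
median-of-ratios offsets computed per assay (RNA and RPF libraries scale
independently). β2 is ΔRNA, β3 is ΔTE; ΔRPF comes from an RPF-only
condition contrast. All fits use the in-house IRLS machinery shared with
the tRNA tests, with a common dispersion pooled within the four design
cells and across genes. Classification at FDR q follows the two-by-two
rule on (padj_rna, padj_te); the finer interaction subclasses
(intensified / buffered / forwarded / exclusive) are deliberately collapsed
to the three-class scheme RNA / Ribo / Ribo&RNA. TE is computed per sample
as RPKM(RPF)/RPKM(RNA), undefined (missing, never infinite) where the RNA
RPKM is zero; the sanity check `te_vs_deltate_check` rank-correlates fitted
ΔTE with the log2 ratio of condition-mean TE.

## Codon usage and the tRNA correlation

RSCU_c = x_c · n / Σ_family x over the family of size n, stop codons
excluded; unused families score 0 for all members. RSCU is computed per
gene and averaged unweighted across genes (matching a per-gene-average
design rather than pooled counts). For comparison with tRNA expression,
both vectors are renormalised so each amino-acid family totals 100 %.
Codon–anticodon pairing is exact Watson–Crick reverse complement; wobble
decoding is not modelled. Codons whose cognate anticodon is absent from the
reference (eight anticodons are missing from high-confidence references and
from the default synthetic gene set) are retained with a tRNA percentage of
0, keeping the vectors alignable; dropping them instead would discard
exactly the codons where decoding pressure is most skewed. The correlation
is pooled Pearson over all paired codons.

## The synthetic-data generator

The generator emulates the targeted study design: two conditions ("tissues")
with 3 replicates each, NB2 count noise with a dispersion of 0.05 shared
across features (typical bulk-RNA-seq biological variability), tRNA gene
sets with 54 distinct cytoplasmic anticodons (one per sense codon plus
selenocysteine, minus the eight anticodons absent from high-confidence
references) and 22 mitochondrial tRNAs, duplicated gene copies to exercise
collapsing, and transcripts of 50–200 codons flanked by 50 nt UTRs.

Footprints are 25–35 nt with a peaked length distribution and per-length
5′→P-site offsets of 12 nt (≤ 29 nt) and 13 nt (≥ 30 nt). Ribosome
positions are sampled proportional to the dwell weight of the codon in the
**A-site** (decoding the A-site codon is the rate-limiting elongation step,
so pausing signal lives there; the site is configurable), with the start
codon boosted 10-fold — a realistic initiation peak for elongation-inhibitor
libraries, and the feature that makes the offset estimator identifiable.
5 % of P-sites are placed uniformly in UTRs so region-fraction QC is
non-degenerate. Matched RNA/RPF tables plant genes in four regulatory
classes: `none`, `rna_only` (both assays shift equally, ΔTE = 0),
`ribo_only` (RPF only), and `both` (independent RNA and TE shifts); gene
base means are log-normal (median 200), baseline TE varies log-normally
(σ = 0.25), and per-sample depths vary log-normally (σ = 0.15) so size
factors do real work.

What the generator does **not** emulate: sequencing errors and FASTQ-level
artefacts, alignment ambiguity in genome space, tRNA modifications and
charging states, position-dependent coverage biases (beyond the initiation
peak), and dispersion heterogeneity across features. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
declared generative model, not robustness to every artefact of real
libraries.

`simulate_occupancy_counts` draws codon-level A-site counts directly from
dwell weights (NB noise around dwell-proportional means), bypassing
footprint placement; it exists for calibration experiments that need
hundreds of replicate datasets cheaply.

## Problem sizes and numerics

The test suite and acceptance script use: 20 k footprints over 50
transcripts for offset recovery; 200 k footprints over 100 transcripts for
dwell recovery (rank correlation of planted versus estimated occupancy
≥ 0.9); 500 simulation rounds for Welch/enrichment null calibration; 2,000
features (200 planted at 4-fold) for DE calibration; 1,000 genes (250 per
class, |log2fc| = 2) for classification recovery; and 200 rounds for the
correlation-recovery check, where noise is calibrated as
σ = sd(RSCU %) · sqrt(1/r² − 1) to plant r = 0.55. These sizes give stable
statistics in seconds per stage on a single core.

IRLS starts from a weighted least-squares fit on log(y + 0.5), caps the
linear predictor at ±30, and declares convergence at a 1e-8 step; fits that
fail to converge yield missing p-values, never a crash. All randomness
derives from a single seed; each generator stage draws from an independent
`SeedSequence([seed, stage])` stream, so identical configurations produce
byte-identical outputs.

## Known limitations

- Exact-substring read assignment ignores sequencing errors entirely.
- The common dispersion is a poor fit for data with strong
  mean–dispersion trends; there is no empirical-Bayes moderation.
- Offset estimation requires an initiation peak and transcript-space
  alignments; spliced genome-space coordinates are out of scope.
- Wobble decoding is not modelled anywhere; the codon–anticodon pairing is
  strict Watson–Crick.
- The classifier's three-class scheme cannot distinguish buffering from
  intensification among `Ribo&RNA` genes.
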