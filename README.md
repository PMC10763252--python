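# translatome

Integrative analysis of the translational machinery from three matched
sequencing assays: mature tRNA sequencing (tRNA abundance), ribosome
profiling (where ribosomes sit and pause), and RNA-seq (transcript
abundance). The package is aimed at researchers asking how tRNA availability
and codon usage shape translation elongation across tissues or conditions —
which tRNAs change, where ribosomes dwell, which genes are regulated
transcriptionally versus translationally, and whether codon usage of
regulated genes tracks cognate tRNA levels.

Every stage is also exercised end-to-end on a built-in synthetic-data
generator with known ground truth, so the statistical machinery is testable
without any external downloads.

## What it computes

**tRNA quantification.** tRNA gene families are heavily duplicated, so
byte-identical mature sequences are collapsed into single representatives;
reads are assigned by exact substring matching (reads ≥ 15 nt; a read
matching *k* records counts 1/*k* to each) and summed up the hierarchy
isodecoder → anticodon → amino acid. Differential expression uses
median-of-ratios size factors

    s_j = median_g ( k_gj / (Π_j' k_gj')^(1/m) ),

a negative-binomial GLM with log link (NB2, Var = μ + αμ², with a common
method-of-moments dispersion pooled across features), Wald tests, and
Benjamini–Hochberg correction at FDR ≤ 0.05.

**Footprint QC and codon occupancy.** For ribosome-protected fragments
(25–35 nt), the per-length P-site offset is the mode of `cds_start −
five_prime_pos` over reads spanning the start codon; P-sites are annotated
into 5′UTR/CDS/3′UTR and reading frames. Codon occupancy at the E/P/A sites
is frequency-normalised, occ_c = N_c / F_c, against codon counts in the CDSs
that received footprints, and reported as percentages; tissue contrasts use
Welch's *t*-test and the all-replicate-pairs ratio of log2(CPM+1) A-site
counts (1 = equal enrichment).

**Translational regulation.** Matched RNA/RPF counts are fitted per gene
with the interaction model

    log μ = β0 + β1·assay + β2·condition + β3·(assay × condition),

where β2 is the transcriptional change (ΔRNA) and the interaction β3 the
change in translational efficiency (ΔTE). Genes are classified at FDR q:
RNA (ΔRNA only), Ribo (ΔTE only), Ribo&RNA (both). TE itself is the
per-sample ratio of RPKM-normalised RPF to RNA counts.

**Codon usage vs tRNA abundance.** Relative synonymous codon usage,
RSCU_c = x_c·n / Σ_family x, is computed per gene and averaged; RSCU and
tRNA expression are each renormalised so every amino-acid family totals
100 %, codons are paired with their exact Watson–Crick cognate anticodons,
and a pooled Pearson correlation is reported.

## Worked example

```python
from translatome.synthetic import SimulationConfig, generate_transcriptome, \
    simulate_footprints
from translatome.qc import estimate_psite_offsets, annotate_psites, \
    region_fractions

cfg = SimulationConfig(seed=42, n_genes=50, reads_per_sample=20_000,
                       read_length_probs={L: 1 / 11 for L in range(25, 36)})
sequences, models = generate_transcriptome(cfg)
footprints, truth = simulate_footprints(sequences, models, cfg,
                                        samples=["liver_1"])

offsets = estimate_psite_offsets(footprints, models)
print("estimated offsets:", offsets)
annotations = annotate_psites(footprints, offsets, models)
print(region_fractions(annotations).round(2))
```

prints

```
estimated offsets: {25: 12, 26: 12, 27: 12, 28: 12, 29: 12, 30: 13,
                    31: 13, 32: 13, 33: 13, 34: 13, 35: 13}
region     utr5   cds  utr3
sample_id
liver_1    2.46  95.0  2.54
```

The generator planted a 12 nt offset for reads ≤ 29 nt and 13 nt for longer
reads, and placed 5 % of P-sites in UTRs as noise; the estimator recovers the
offsets exactly for every read length, and 95 % of P-sites fall in the coding
sequence, as planted. A full synthetic run of every stage — reference
collapsing through the RSCU–tRNA correlation, with all tables and a manifest
— is one command:

```bash
translatome run-all --seed 42 --outdir results/
```

Individual stages are available as subcommands (`trna-collapse`, `trna-de`,
`ribo-qc`, `occupancy`, `enrich`, `deltate`, `rscu`, `correlate`); see
`translatome --help`.

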