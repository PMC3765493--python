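# aeikit

Toolkit for measuring **allelic expression imbalance (AEI)** from RNA-seq.
In a heterozygous individual the two alleles of a gene can be transcribed at
different rates; the ratio of reads carrying each allele at a heterozygous
SNP is a direct, within-sample readout of *cis*-acting regulation, RNA
editing, imprinting or loss of heterozygosity. Measuring it well from
short-read data is harder than it looks: aligners score the non-reference
allele as a mismatch, so variant-carrying reads are systematically lost and
allelic ratios are inflated away from 1 ("reference mapping bias").

`aeikit` implements a complete, testable version of that measurement
pipeline for bulk or single-cell transcriptomics:

- **Bias-attenuating references** — genome-wide masking of catalogued SNPs
  with IUPAC ambiguity characters (A/G → R, C/T → Y, …) so either allele
  matches the reference, and targeted allele switching for panel-based
  bias estimation.
- **Filtered allelic counts** — pileup of ref/var/other reads at catalogued
  heterozygous SNPs from SAM, retention of sites with ≥ 3 reads per allele
  and a minor-allele fraction ≥ 5%, gene/region annotation by interval
  overlap (BED or GFF3), and merging of SNPs within 100 bp into single
  observations (they likely sit on the same library fragment).
- **Ratio math and AEI calling** — ratios are folded onto the ≥ 1 scale as
  10^|log₁₀(ref/var)| (phase is unknown, so 2-fold and 0.5-fold carry the
  same information and combine to 2-fold), then combined per gene × sample
  (mean, SD, heterogeneity). A gene is called under a permissive rule
  (mean fold ≥ 2 with ≥ 2 observations) or two stringent rules
  (mean − 2·SD ≥ 1.5; or SD ≤ mean/3 with mean ≥ 2).
- **Method comparison** — OLS of corrected vs standard log ratios with
  fold predictions from the fitted line, a logistic harness (with AIC
  model comparison) for predicting orthogonal-assay confirmation from the
  logit score ln(major/minor), and cDNA/gDNA peak-height normalisation for
  primer-extension (SNaPshot) assays.
- **RNA-editing survey** — per-site edited fractions across samples,
  retention filters (support in a minimum number of samples per condition
  group, average depth > 10), exclusion of probable reference-sequence
  errors (confidence interval reaching 100% variant), and cross-condition
  comparisons of editing extent (Pearson r²) and variability (paired
  Wilcoxon on per-site SEMs).
- **Ground-truthed simulation** — toy genomes, SNP catalogs, placed SAM
  reads with a one-parameter bias model (each variant read lost with
  probability β, so the expected observed ratio is true_ratio/(1−β)), and
  two-condition editing panels. Every stage of the pipeline is testable
  against planted truth without downloading anything.

## Worked example

`examples/02_bias_simulation.py` simulates balanced expression
(true ratio 1.0) at 200 SNPs with a per-read variant loss of β = 0.33,
counts alleles from the simulated SAM files and regresses the corrected
log ratios on the standard ones:

```
sites simulated: 200, true ref/var ratio: 1.0
standard-reference mean observed ratio: 1.503 (bias model predicts 1/(1-beta) = 1.493)
masked-reference mean observed ratio:   1.007 (predicts 1.0)
regression of masked on standard log10 folded ratios: slope -0.043, intercept 0.041, r^2 0.006
a 3-fold standard ratio corresponds to a 1.05-fold masked ratio
```

Under pure reference bias the standard alignment inflates a balanced ratio
to ≈ 1.5-fold — comfortably past naive AEI thresholds — while the masked
alignment recovers 1.0; the near-zero slope says the apparent "signal" in
the standard alignment carries no information about the corrected ratio.
The other examples cover reference construction (`01`), gene-level AEI
calling on planted imbalances (`03`), and the editing survey (`04`),
including the bundled panel of 12 published brain editing sites where the
two condition groups correlate at r² = 0.88 and their per-site variability
does not differ (Wilcoxon p = 0.18).

A CLI mirrors the library for shell use:

```bash
aeikit simulate --out-dir fixtures/ --seed 7
aeikit mask-ref --fasta fixtures/genome.fa --variants fixtures/sites.tsv --out masked.fa
aeikit count --sam fixtures/reads_masked.sam --sites fixtures/sites.tsv \
             --genes fixtures/genes.bed --out counts.tsv
aeikit aei-call --counts counts.tsv --mode permissive --out aei.tsv
aeikit run --config pipeline.cfg   # key=value file, all thresholds echoed
```

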