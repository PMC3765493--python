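# Methods

## The measurement problem

At a heterozygous SNP, the ratio of RNA-seq reads carrying each allele
estimates the relative transcription of the two haplotypes in one sample.
Because the aligner scores the non-reference allele as a mismatch, reads
carrying it are mapped less often; observed ref/var ratios are therefore
biased upward even when the two alleles are expressed equally. `aeikit`
implements two countermeasures at the reference-genome level and a
downstream statistical pipeline whose every stage can be validated against
simulated ground truth.

## Reference construction

**IUPAC masking** replaces each catalogued biallelic SNP position with the
two-base ambiguity character covering exactly the ref and alt alleles
(R, Y, S, W, K, M). Masking is restricted to biallelic single-nucleotide
substitutions; indels and multiallelic records in a VCF are skipped with a
logged count. A catalog position whose reference allele disagrees with the
genome base is skipped with a per-site audit record rather than aborting
(public catalogs routinely carry strand or assembly discrepancies); a
`strict` flag upgrades this to an error. Output FASTA is written at a
fixed 60-column width, uppercase.

**Allele switching** substitutes the variant allele into the reference at
a target panel. Bias is then measurable by comparing reference-allele
counts between the standard and switched alignments; applying the switch
twice with swapped alleles restores the original genome exactly, which the
tests exploit as an involution check.

Coordinates are 1-based everywhere internally (the VCF convention); BED
input is converted from 0-based half-open on read.

## Counting and filtering

Pileup assigns each mapped, non-secondary read overlapping a site to
ref/var/other by its base at the position; reads with a deletion or clip
there contribute to none. Defaults MAPQ ≥ 1 and base quality ≥ 13, both
configurable. No duplicate-read removal is performed.

A site enters ratio analysis only if both alleles have ≥ 3 supporting
reads (≥ 6 informative total) and the minor allele makes up ≥ 5% of
informative reads. Only exonic sites (including UTRs and ncRNA exons)
proceed; a site inside intervals of several genes contributes one
observation per gene rather than being dropped, flagged in output, so
gene-level combination stays computable for each. UTR and coding-exon
sites of a gene are pooled.

SNPs within 100 bp of each other likely sit on the same library fragment
and are not independent; their folded ratios are averaged into a single
observation. Clustering is greedy left-to-right, anchored on the first SNP
of the cluster: a new cluster starts when a site lies more than 100 bp
from the anchor. This rule is deterministic and order-independent given
position-sorted input; other anchorings (centroid, chaining) would differ
only for pathological SNP spacings.

## Ratio mathematics and AEI calls

Phase is unknown, so ratios are folded: `folded = 10^|log10(ref/var)|`,
computed as major/minor so the result is bit-identical under swapping the
counts. The logit score is ln(major/minor). Gene × sample combination
takes the arithmetic mean and SD (n − 1 denominator) of the merged folded
ratios on the linear fold scale — the stringent 2·SD rule is stated on
that scale, and reported per-gene extremes are linear folds — while the
mean log10 ratio is stored for diagnostics. The folding worked example
(raw 2.0 and 0.5 combining to 2.0) holds under either convention.

Heterogeneity is summarised by an equal-weight statistic
Q = Σ(yᵢ − ȳ)² on the log10 scale. This is a stand-in for an
inverse-variance-weighted Cochran's Q: after window merging the
observation-level count variances are no longer available, so equal
weights are the defensible choice; reports label the statistic
accordingly.

Three call rules, all pure functions of the summary fields:

- **permissive**: mean fold ≥ 2 and ≥ 2 merged observations. Requiring a
  second observation suppresses single-SNP artifacts at low depth.
- **stringent (2·SD)**: mean − 2·SD ≥ 1.5. Genes with one observation
  have no SD and are ineligible.
- **stringent (SD/3)**: SD ≤ mean/3 and mean ≥ 2.

Thresholds are configuration, not inference; no multiple-testing
correction is applied anywhere, because the calls are screening rules
rather than significance statements.

## Method comparison

Corrected log10 ratios are regressed on standard-alignment log10 ratios by
OLS with an intercept; `predicted_fold(f)` evaluates the fitted line at a
standard fold f, e.g. mapping a 3-fold standard ratio to its corrected
equivalent. The logistic harness fits a maximum-likelihood model
predicting whether an orthogonal single-gene assay confirms ≥ 1.5-fold
AEI, from the logit score plus optional covariates (number of additional
SNPs × logit score as an interaction, heterogeneity); AIC supports
comparison across feature sets. Perfect separation is flagged (detected
from exploding standard errors or a raised fit error) and AIC reported as
unavailable. The logit uses the natural log; base is configurable in the
sense that the score is a monotone transform, and only differences of AIC
are interpreted.

SNaPshot normalisation divides the cDNA peak-height ratio by the gDNA
ratio of the same two alleles: gDNA is a true 1:1 template, so dye and
incorporation biases cancel and the quotient estimates the allelic mRNA
ratio.

Linear meta-analytic pooling across samples is deliberately out of scope;
only the logistic harness is provided for cross-method prediction.

## RNA-editing survey

Editing is quantified at catalogued sites only (no de novo discovery) as
edited/total per sample; "% edited" for a site is the mean of per-sample
fractions (the SEM across samples is reported alongside, which fixes this
convention over pooled counts). Retention requires variant reads in a
minimum number of samples per condition group — defaults 5 of 10 regions
and 8 of 13 individuals, the stricter of two published variants of the
rule, exposed as a parameter — and average depth strictly greater than 10
reads in every group. Sites flagged for pseudogene/homologous-sequence
mapping ambiguity are excluded via an input flag column; homology search
itself is out of scope.

Sites where all samples express (nearly) only the variant allele are
better explained by a wrong reference base than by editing. The exclusion
builds a two-sided t-interval on the per-sample fractions (mean ±
t·SEM) and removes the site when the upper bound reaches 100%; a pooled
exact binomial interval is available behind a flag. A single covered
sample is not evaluable and is retained with a warning.

Cross-condition comparisons: Pearson r and r² on per-site mean fractions;
variability compared by a paired two-sided Wilcoxon signed-rank test on
per-site SEMs (exact null at small panel sizes, robust to the heavy tails
SEMs show at n ≈ 12), with an F-type variance-ratio alternative behind a
flag.

## Simulation model

The generator is the package's ground truth. Per site and sample, total
informative reads ~ Poisson(depth) (a fixed-depth switch exists for exact
tests); each read is reference with probability r/(1+r) for true fold r;
each variant read is then lost independently with probability β. Hence
E[observed ratio] = r/(1−β) — the closed form every bias test checks
against. Read simulation places each read uniformly over the positions
covering its site, with the site base set to the sampled allele and all
other bases copied from the genome; SNPs are spaced more than a read
length apart so planted counts and pileup tallies are identical by
construction. Standard-reference mode applies the β-loss; masked-reference
mode forces β = 0, i.e. the ambiguity character is assumed to match both
alleles at zero penalty. That assumption — and the absence of mismatch
scoring, splicing, sequencing error, duplicate fragments and homologous
multi-mapping — bounds what passing tests show about real data: they
validate the arithmetic and the direction and magnitude of the bias
correction under the stated model, not aligner behaviour on real reads.

Defaults mirror the targeted-panel study scale: 58 genes with 1–6 SNPs
each (~190 sites), mean depth 60 (inside the reported 24–409 reads/SNP
range), 9 samples, β = 0.33 — the loss rate that reproduces the observed
~1.5× inflation of standard-alignment ratios. The editing panel defaults
to 12 sites with true fractions spanning 0.2–1.0 across condition groups
of 10 and 13 samples at mean depth 30. Test and example runs scale depth
and site counts per check (e.g. 200 sites at depth 500 for bias recovery,
10⁵ for closed-form checks) to keep sampling error well inside the
asserted tolerances. All generators are pure functions of (config, seed);
fixed seeds give byte-identical outputs.

## Known limitations

- The bias model is a single per-read loss probability; it reproduces the
  mean inflation of ratios but not locus-specific bias from paralogy,
  splice structure or indel proximity.
- Gene annotation is plain interval overlap; no transcript-model
  awareness, no annotation-database integration.
- The heterogeneity statistic is unweighted (see above).
- The reference-error exclusion treats per-sample fractions as
  approximately normal; at very low depth the binomial-pooled flag is the
  safer variant.
- AEI calls are screening thresholds without error control; depth-aware
  significance testing of single-SNP AEI is intentionally not provided.
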