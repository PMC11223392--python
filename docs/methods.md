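# Methods

`xplatcord` re-implements, as a tested pipeline on synthetic data with known
ground truth, a cross-platform transcriptomics concordance analysis: two
platforms (a targeted-sequencing assay producing counts, and a microarray
producing log2 intensities) measure the same five-condition exposure design —
untreated (UT), clean-air control (CA), and three dose levels (LD, MD, HD) —
and their differentially expressed genes (DEGs) are harmonized through probe
panels, compared, and validated against an RT-qPCR panel.

## The synthetic study

The generator (`xplatcord.synthdata`) is the package's definition of the study
conditions; every statistical claim the tests make is relative to it.

**Ground truth.** Each of `n_genes` (default 2000) genes gets a base abundance
(expected CA counts at the reference library size) drawn log-normal
(`sigma = 1.6` on the natural log scale) and rescaled so abundances sum to the
mean library size. A fraction `frac_de` (default 0.05, of the order of the
1–3% of probes a mild airway exposure deregulates) is differentially
expressed, with one sign per gene and a dose-monotone magnitude profile:
HD carries the full effect, MD 0.6x, LD 0.3x. Full-effect magnitudes are
0.6 + Gamma(shape 2, scale 0.75) log2 units, so every DE gene clears both
platforms' fold-change cutoffs at HD while the tail reaches the 5–7 log2FC
range a strong responder shows in sequencing data.

**Mass balance.** DE signs are split evenly in count, but assigned by a greedy
rule that cancels the abundance-weighted gain and loss of transcript mass
(total expected expression is conserved under treatment). This is deliberate:
total-count (CPM) normalization — the normalization this pipeline inherits —
is only unbiased when the treatment does not change total mRNA mass. Without
the balance, the net mass change (dominated by strongly upregulated abundant
genes) propagates into every gene's estimated log2FC as a constant shift of
0.2–0.5 log2 units, and no total-count method can recover the truth.
A consequence worth knowing: because a gene's mass gain (2^m − 1) always
exceeds its loss (1 − 2^−m), conservation with an even count split forces
downregulated genes toward higher abundance and somewhat larger magnitudes,
so *called* DEG sets skew mildly toward downregulation even though the truth
table is exactly even. Real data are under no such constraint.

**Counts (platform B).** Per-sample library sizes are log-normal with mean
6.2 million (a typical targeted-sequencing depth for this design) and CV 0.15.
Gene counts are negative binomial via a gamma–Poisson mixture with
`Var = mu + alpha mu^2`, default dispersion `alpha = 0.05`; below
`alpha = 1e-8` the draw degenerates to Poisson. Means scale multiplicatively
with library size and `2^log2fc(condition)`.

**Intensities (platform A).** Log2 intensities with baseline
`4 + 0.6 log2(CPM + 1)` (mapping abundances into the usual 4–15 window),
condition means offset by `compression x log2fc` (default compression 0.5,
matching the roughly halved dynamic range of fluorescence read-out), and
Gaussian noise (sd 0.25 log2 units).

**CT values.** `CT = 38 − log2(abundance in CPM) + noise` (sd 0.15 cycles), so
doubling the template lowers CT by exactly one cycle; wells above the
detection limit (40 cycles) are "not detected". A configurable number of
stable, highly expressed non-DE genes (default 8, simulated with 0.3x noise)
serve as reference-gene candidates.

**Panels.** Each gene gets 1–3 transcripts on a toy chromosome; a
`panel_overlap_frac` of genes carries probes on both panels sharing at least
one transcript id (with Ensembl-style version suffixes to exercise version
stripping). A `flawed_probe_frac` of shared genes emulates a mis-designed
sequencing probe targeting an unexpressed isoform: its counts are flat
background (1% of base) at every dose, while the array still sees the effect.
The array panel additionally carries unmappable probes under the non-coding
label vocabulary (Non-coding, Precursor_microRNA, Pseudogene, Ribosomal,
Small_RNA, tRNA, Unassigned).

**Determinism.** Every output object draws from its own RNG stream split off
the master seed (`SeedSequence([seed, stream_id])`), so regenerating one
object never perturbs another, and a config (including seed) pins every table
bit-for-bit.

What the generator does *not* emulate: batch effects, probe-sequence
thermodynamics, read-level structure, between-gene correlation, and
platform-specific background/saturation. Passing tests therefore demonstrate
correctness of the analysis chain under the stated model, not robustness to
those real-data features.

## Differential expression

**Sequencing (NB Wald).** Size factors are the CPM factors
(library total / 1e6), mirroring a DESeq2 run whose normalization factors are
set to the CPM factors. Per gene, group abundance is the mean of
size-factor-normalized counts (so the log2FC sign always equals the sign of
the CPM mean difference); dispersion is a pooled method-of-moments estimate
`alpha = sum[((k − mu)^2 − mu)/mu^2] / (n − 2)` floored at 1e-8 and capped at
10; the variance of log q follows by the delta method; and the Wald statistic
for `log(qB/qA)` is referred to a t distribution with `nA + nB − 2` degrees of
freedom — a small-sample moderation that brings the null rejection rate to
4–6% at the 5% level with three replicates (a normal reference is
anticonservative here). Genes with all-zero counts get p = 1 and log2FC = 0;
an empty group receives a half-count continuity correction. This estimator is
a transparent stand-in for DESeq2: no per-gene equality with DESeq2 is
claimed, but on simulated data its log2FC estimates agree with `pydeseq2` to
a median absolute difference below 0.05 (cross-checked in the test suite).
DEG rule: BH-adjusted FDR < 0.05 and |log2FC| > 0.5, both strict.

**Array (per-gene t-test).** Two-sample t-test on log2 intensities per gene,
pooled variance by default (Welch behind a flag); log2FC is the mean
difference, and the signed linear fold change is `sign(lfc) * 2^|lfc|`. The
DEG rule is the microarray console convention: unadjusted p < 0.05 and
|linear FC| > 2 (strict). A BH-adjusted column is computed alongside for
reference but never enters the call — multiple-testing correction on a
whole-transcriptome array panel suppresses nearly everything, which is
precisely the platform-workflow asymmetry the concordance analysis studies.

## Probe-panel harmonization

Panels join through shared transcript ids (version suffixes stripped by
default): every (A, B) probe pair sharing at least one transcript forms one
deduplicated pair in the N-to-N sense; an optional strict 1-to-1 filter drops
probes participating in more than one pair. Coverage is accounted per probe
label with a column-sum Total row. Probe alignments are tested for perfect
transcript coverage: chromosome and strand must match, every block must lie
inside a single exon, and blocks must be contiguous in spliced transcript
coordinates — a block boundary may only coincide with an exon junction. This
rule is verified against a per-base spliced-projection oracle on randomized
gene models. Probe signals are summarized to genes by summing counts or
averaging log2 intensities. Coordinates are 0-based half-open internally;
GTF I/O converts to 1-based inclusive.

## qPCR chain

Detection calls flag wells above the CT limit. Reference genes are ranked by
the model-based stability of Andersen et al. (NormFinder): per condition
group, CT values are double-centered (gene and sample effects removed); the
per-gene group deviation is shrunken by its sampling variance
(`d * gamma^2/(gamma^2 + s^2/n)`, with `gamma^2` the method-of-moments
between-group variance); stability is the group mean of |shrunken deviation|
plus the intragroup standard error, lower = more stable, ties broken by gene
id. Where published ports differ in constants, the published model wins;
the package's claim is rank agreement on engineered fixtures, not decimal
parity with any specific implementation.

Quantification is the comparative ddCT method with amplification efficiency
fixed at 2: `dCT = CT(gene) − mean CT(references)` per well, `ddCT` is the
condition-vs-control difference of mean dCT, `log2FC = −ddCT`,
`FC = 2^−ddCT`. Significance per gene comes from the linear model
`dCT ~ condition` (pooled residual variance across all groups, t test of the
contrast-vs-control coefficient); a group with fewer than two detected wells
yields no p-value and `detected = False`. Degenerate zero-variance fits map
to p = 0 for a nonzero difference and p = 1 otherwise, so noise-free data
behave as the limit of vanishing noise.

## Concordance and validation classification

Overlap bookkeeping is inclusion–exclusion on DEG flags over the shared gene
universe; "conflicting" counts union DEGs whose two platform log2FC signs
differ (this convention makes the overlap, union, quadrant and conflict
numbers mutually consistent); direction-split overlap rows count only
sign-agreeing genes. Quadrant fractions use one decimal (two where
conventionally printed), overlap shares round to integers, all rounding half
away from zero. Spearman correlations (average ranks) are reported for both
the union and the overlap set.

Validation classifies each DEG against qPCR at the validated condition at two
granularities. The overall category demands direction agreement with *both*
platforms' fold-change directions (a gene is "confirmed" only when all three
systems agree; conflicts are subtyped by which platform the qPCR call
opposes, using both platforms' fold-change directions regardless of DEG
flags). The four summary columns — union, array (genesets I+II), sequencing
(genesets I+III), both (geneset I) — evaluate categories against their own
column's platform(s), so a sequencing-only DEG whose qPCR call matches the
sequencing direction but opposes the array fold change is confirmed in the
sequencing column yet conflicting overall. "Conflicting" always requires qPCR
significance; non-significant genes are "not confirmed" whatever their
direction. Percentages are reported against the full column N (including
not-detected genes) with a detected-only variant alongside, since published
validation tables mix both conventions.

## QC

PCA is a gene-centered SVD with a deterministic sign convention (largest
loading positive). Outlier flags are advisory: a sample is flagged when its
distance to its condition centroid in score space exceeds
median + 5 x MAD of all within-condition distances — a deliberately blunt,
scale-invariant rule; removal stays a user decision. The dose-dependency
heatmap clusters the (platform x dose) log2FC columns by Euclidean
complete linkage implemented in-repo so ties can break lexicographically for
reproducible dendrograms; it is checked against both a naive cubic
agglomeration and scipy on tie-free inputs.

## Problem sizes and tolerances

The test suite and the acceptance script run everything at desk scale, chosen
as the smallest sizes at which each claim is statistically meaningful:
null calibration at 500–1000 features with 3 replicates (band 2–9% at the
nominal 5%); NB parameter recovery at 500 genes, 30 replicates, dispersion
0.05 (the ±0.2 band cannot be met at 10 replicates by any unbiased estimator,
since the sampling SD of log2FC alone is `sqrt(2 x 0.05/10)/ln 2 = 0.14`);
the noise-free chain at 400 genes and 1e8 counts per sample so sampling error
is well inside the 0.05 identity tolerance; and the flawed-probe scenario at
800 genes with 10% flawed shared probes. Randomized oracle batteries run
1000 cases each. The full suite completes in well under a minute of compute
per criterion.
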