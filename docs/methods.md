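# Methods

## The model system

The package analyses a serial-passage culture model of RPE wound response:
primary cultures from three donors are either minimally passaged (P0) or
repeatedly harvested at subconfluence (P4/P5, a proxy for sustained wound
stimulus), replated, and profiled at 3 days (still subconfluent) and at
16, 32 and 64 days post-confluence. Repeated passage causes a persistent
loss of the RPE expression program (signature and differentiation genes
down), gain of a wound/mesenchymal program (up), and reduced
proliferation; treating passaged cultures with a TGFβ-receptor kinase
inhibitor (A-83-01) moves much of the transcriptome back toward the P0
state. The analysis stages quantify: which genes change with passage
(donor-consistent fold-change criterion), how many such calls are expected
by chance (empirical inter-donor null), how completely treatment restores
them (recovery fraction), and whether externally defined disease gene
lists are over-represented among them in the matching direction
(directional Fisher enrichment).

## Differential expression criterion

A gene is called at a time point iff every donor's intra-donor ratio
(alternative over reference condition) lies on the same side of 1 with
magnitude ≥ `min_each` (default 1.5) and the arithmetic mean of the
magnitudes is ≥ `min_mean` (default 2.0); both boundaries inclusive.
Choices made where the rule is underdetermined:

* **Direction consistency is required.** A gene whose donors disagree in
  sign has no meaningful "mean fold change"; such genes are `none`.
* **Arithmetic mean of ratio magnitudes**, read literally from "mean fold
  change"; a geometric-mean switch (`mean_kind="geometric"`) is provided.
* **Union over time points** defines passage dependence; genes called up
  at one time point and down at another are `ambiguous` and belong to
  neither set, since downstream directional matching needs a single sign.

## Empirical inter-donor null

Applying the criterion to donor-vs-donor comparisons *within* one
condition estimates its chance-call rate. With donors (A, B, C) we use the
three unordered pairs with consistent orientation — (A,B), (A,C), (B,C) —
as pseudo-donor pairs. A cyclic pairing (A,B), (B,C), (C,A) may look more
symmetric (each donor used once on each side) but is structurally silent
for this criterion: its three log folds sum to zero identically, so they
can never share a sign and the estimate is always 0. The unordered-pair
set does register chance calls — exactly when one donor is a consistent
outlier — which is the failure mode the criterion is exposed to in real
data. The cyclic variant is retained as an option (`pairing="cyclic"`)
with its degeneracy documented.

## Recovery fraction

r = (treated − baseline)/(reference − baseline), computed on log2
expression (fold-change space treats up- and down-regulated genes
symmetrically); a linear-scale option is retained for sensitivity
analysis. Genes with |reference − baseline| < 0.1 log2 units are flagged
degenerate and excluded — passage-dependent genes clear this by
construction and the guard prevents division blow-ups. r is reported
unclipped (overshoot > 1 and worsening < 0 are informative); thresholds
are applied as r ≥ t, so over-recovery counts as recovered.

## Enrichment and the fold + ANOVA screen

Fisher's exact test is one-sided (upper tail, P(X ≥ k)): the question
asked is over-representation. The odds ratio is the sample cross-product
ratio with a Haldane 0.5 correction when any cell is zero. The candidate
screen for curated panels (TGFβ pathway, disease risk genes) passes a gene
when any time point shows |log2 group-mean ratio| ≥ log2(2) together with
one-way ANOVA p ≤ 0.05 across the two passage groups (n = 3 per group; the
two-group F equals the squared pooled t, which the tests verify). Group
ratios are computed from linear-scale means, the ANOVA on log2 values.

## Preprocessing

**Arrays.** Stage order is fixed: negative-control background subtraction
→ (optional) lowess dye correction → replicate-probe averaging → quantile
normalization → detection filter → probe-to-gene collapse. Decisions:

* Net intensities are floored at 1.0: background subtraction can produce
  non-positive values and downstream fold changes need positivity.
* Per-sample background = the mean of that sample's negative-control
  intensities, reused by the detection filter (net ≥ 2× background in ≥ 1
  sample keeps a probe; the boundary is inclusive, i.e. equality keeps).
* Lowess uses span 0.3 with 3 robustness iterations (standard two-color
  defaults, configurable); the fit of M on A is subtracted and channels
  are reconstructed from corrected M and unchanged A.
* Quantile normalization maps each column onto the mean-of-sorted-columns
  reference; ties receive the mean of the reference values their average
  rank spans, which makes the transform idempotent.
* Probe→gene collapse keeps the probe with the highest mean intensity
  across samples; ties break to the lexicographically smallest probe id
  for determinism.
* The scanner's own global background subtraction and dye handling are
  treated as upstream of the input table; the single-channel synthetic
  path therefore skips the lowess stage, which activates only when a
  second channel matrix is supplied.

**RNA-seq.** TMM factors follow the published trimmed-mean-of-M-values
method: reference sample = the one whose 75th-percentile count/library
ratio is closest to the mean; per sample, genes zero in either sample are
excluded, the top/bottom 30 % of M and 5 % of A are rank-trimmed, and the
factor is the precision-weighted (1/variance, binomial delta-method) mean
of the surviving M values; factors are scaled to geometric mean 1. The
implementation is cross-checked against edgeR's `calcNormFactors` to
1e-10 in the test suite. RPM = count / (library size × factor) × 1e6; the
expression filter keeps genes with RPM ≥ 1 in ≥ 3 samples. For
ratio-based downstream statistics the pipeline clips RPM at 0.5 (the
counting analogue of the array net floor). The negative-binomial
differential test used upstream of some published gene lists is *not*
re-implemented; downstream stages accept any external gene list alongside
the internal fold-change caller.

**qPCR.** Duplicate wells are averaged on the Ct scale (the natural scale
of the measurement); quantities assume 100 % efficiency (Q = 2^−Ct) and
are normalized to the geometric mean of RPL15, NDUFA11 and UBB, i.e.
2^(mean Ct_hk − Ct_gene), which is exactly shift-invariant per sample.

## Synthetic data generator

The generator emulates the study design so that planted ground truth is
available for every stage:

* **Design:** 3 donors × (P0, P5) × days {3, 16, 32, 64} for arrays;
  3 donors × (P0, P4, P4 + inhibitor) at day 32 for RNA-seq; the two arms
  of one config share gene identities, classes and planted effects.
* **Gene classes and effects:** fractions rpe 0.15 (down with passage),
  wound 0.15 (up), cell_cycle 0.05 (down), housekeeping 0.05 and null
  0.60 (no effect) — together ~1/3 of genes passage-dependent, split
  roughly evenly between directions, matching the observed scale of the
  response in this model; |log2FC| = 2 per effect class so planted effects
  clear the 2-fold calling threshold.
* **Hierarchy of variation:** per-donor, per-gene random intercepts
  (`donor_sd`, default 0.20 log2) are drawn once and shared across
  conditions — intra-donor fold changes cancel them, inter-donor
  comparisons do not, which is precisely the structure the DE criterion
  and its null exploit. Residual biological noise (`residual_sd`, 0.25
  log2) is per sample; arrays add per-probe offsets (SD 0.5) and
  technical noise (SD 0.10).
* **Arrays:** raw = additive background (mean 50, SD 5) + 2^(level +
  probe offset + technical noise); negative controls carry background
  only, making the 2×-background detection filter meaningful. ~20,000
  probes: 12,000 genes at 1–3 probes each, a block of 200 probes
  replicated 10×, 300 negative controls.
* **RNA-seq:** negative-binomial counts (dispersion 0.05, library size
  2×10⁶) around library-scaled expected proportions; dispersion → 0
  recovers the Poisson limit (tested by moment matching).
* **Rescue:** the treated arm moves each rescued gene's expected log2
  level fully back to P0 (`level_treated = level_untreated + r·(level_P0 −
  level_untreated)`, r = 1 for rescued genes, else 0); the rescued set is
  a random `rescue_fraction` (default 0.87) of affected genes. This makes
  the recovery statistic's ground truth exact: with low noise, the
  percentage of genes recovering ≥ 25 % equals the rescue fraction.

**What the generator does not emulate:** correlated gene modules,
time-profile shapes (planted effects are constant across time points),
dye-swap structure, probe sequence effects, batch effects, and outlier
samples. Passing tests therefore demonstrate correctness of the
statistics under the planted model, not robustness to every artifact of
real array or sequencing data.

## Problem sizes and determinism

The default generator size (12,000 genes / ~20,000 probes) runs the full
pipeline in a few seconds; tests use 200–10,000 genes per case so the
whole suite stays fast. All randomness flows through
`numpy.random.default_rng` seeded from the config (default seed 17,
recorded in every output's provenance header); fixed seeds give
bit-identical tables and reports.

## Known limitations

* The recovery formula is this package's pinned definition; published
  summaries of treatment rescue do not always state one, so absolute
  percentages from other analyses may differ in the degenerate-gene
  handling and scale choice.
* The empirical null with three donors rests on three pseudo-comparisons;
  it estimates an expected count, not a distribution, and is itself noisy
  at small counts.
* The ANOVA screen with n = 3 per group has limited power and assumes
  approximate log-normality within groups.
* Quantile normalization assumes the compared samples share an intensity
  distribution; wholesale distributional shifts (e.g. global expression
  amplification) would be normalized away.
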