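# rpewound

Analysis toolkit for passage-dependent transcriptome changes in cultured
retinal pigmented epithelial (RPE) cells — a serial-passage "wound
stimulus" model in which repeatedly passaged cells lose the capacity to
re-differentiate, switch to a persistent mesenchymal state, and can be
largely rescued by TGFβ-receptor kinase inhibition. The package implements
the complete expression-analysis pipeline for this design and a synthetic
data generator that plants the full donor/passage/time/treatment structure,
so every stage can be exercised and verified offline.

## What it computes

**Donor-consistent fold-change DE.** For gene *g* with per-donor expression
*a_d* (reference condition, e.g. P0) and *b_d* (alternative, e.g. P5), the
per-donor ratios *r_d = b_d / a_d* must all lie on the same side of 1, with
direction-consistent magnitudes *f_d* (= *r_d* or 1/*r_d*). The gene is
called at a time point iff

&nbsp;&nbsp;&nbsp;&nbsp;min_d *f_d* ≥ 1.5  and  mean_d *f_d* ≥ 2.0,

and is *passage-dependent* if called at ≥ 1 of the four time points
(3, 16, 32, 64 days). Genes called in both directions at different time
points are flagged ambiguous and excluded.

**Empirical inter-donor null.** The same criterion applied to the
comparisons between donors *within* one condition — (A,B), (A,C), (B,C) as
pseudo-donor pairs — where every call is chance. This yields the
expected-by-chance count under the observed donor and residual variation.

**Treatment recovery.** For each passage-dependent gene, on log2
expression,

&nbsp;&nbsp;&nbsp;&nbsp;*r* = (treated − baseline) / (reference − baseline),

with reference = mean P0, baseline = mean untreated passaged, treated =
mean inhibitor-treated level; the report gives the percentage of genes
with *r* ≥ 0.25 and ≥ 0.50.

**Directional enrichment.** Disease gene lists tagged up/down are matched
only to the DE set of the same direction, restricted to the expressed-gene
universe, and tested with a one-sided Fisher's exact test (upper-tail
hypergeometric), odds ratio from the 2×2 cross product (Haldane-corrected
at zero cells).

**Preprocessing.** Two-color arrays: negative-control background
subtraction (floored at 1.0), optional lowess M–A dye correction,
averaging of the 10× replicate-probe block, quantile normalization,
detection filter (net ≥ 2× background in ≥ 1 sample), and probe→gene
collapse by highest mean intensity. RNA-seq: TMM scaling factors
(trimmed mean of M-values; verified against edgeR to 1e-10), counts per
million, and the RPM ≥ 1 in ≥ 3 samples expression filter. qPCR: 2^(−Ct)
quantities normalized to the geometric mean of RPL15, NDUFA11 and UBB.

## Worked example

```python
from rpewound import (SimulationConfig, simulate_gene_level,
                      de_call_table, empirical_null_counts)

cfg = SimulationConfig(n_genes=6000, seed=17)
expr, samples, truth = simulate_gene_level(cfg)

table = de_call_table(expr, samples)           # P5 vs P0, per time point
est = empirical_null_counts(expr, samples, {"passage": "P0", "day": 3})
print(len(table.up_genes), len(table.down_genes), est.count)
```

prints `900 1200 5`: of 6,000 simulated genes, 900 are called up and 1,200
down with passage (exactly the planted wound-response and RPE/cell-cycle
classes at these noise levels), while applying the same criterion between
donors within the day-3 P0 condition — where no real effect exists — calls
only 5 genes, the expected-by-chance rate. Running the recovery example
(`python examples/03_rnaseq_and_recovery.py`) then reports

```
2015 passage-dependent genes (P4 vs P0)
  88.1 % of genes recovered >= 25 %
  86.6 % of genes recovered >= 50 %
```

matching the generator's planted rescue fraction of 0.87. The other
scripts in `examples/` demonstrate array preprocessing, directional
enrichment, qPCR quantification and the one-shot pipeline; the same
stages are exposed as a thin CLI (`rpewound simulate|preprocess-array|
preprocess-rnaseq|de-call|null-estimate|recovery|enrich|qpcr|run`).

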