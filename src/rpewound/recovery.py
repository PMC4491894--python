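"""Treatment recovery toward the P0 reference, plus heatmap-style metrics.

For each passage-dependent gene the recovery fraction is

    r = (treated - baseline) / (reference - baseline)

on log2 expression, where *reference* is the mean differentiated (P0)
level, *baseline* the mean untreated passaged level and *treated* the mean
inhibitor-treated level. r = 0 means no movement, r = 1 full restoration;
values outside [0, 1] (overshoot, worsening) are reported unclipped.
Summaries give the percentage of genes at or above each recovery threshold
(defaults 25 % and 50 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEGENERACY_TOL = 0.1  # log2 units: genes whose reference ~ baseline are excluded


class RecoveryError(ValueError):
    pass


def recovery_fraction(reference: pd.Series, baseline: pd.Series,
                      treated: pd.Series, scale: str = "log2",
                      degeneracy_tol: float = DEGENERACY_TOL) -> pd.DataFrame:
    """Per-gene recovery fraction on the chosen scale.

    Inputs are per-gene mean expression on the linear scale; with
    ``scale="log2"`` (default) they are log-transformed first, so recovery
    is measured in fold-change space. Genes whose reference and baseline
    levels differ by less than ``degeneracy_tol`` (on the working scale)
    are flagged degenerate and carry ``r = NaN``.
    """
    if not (reference.index.equals(baseline.index)
            and reference.index.equals(treated.index)):
        raise RecoveryError("gene lists of reference/baseline/treated differ")
    if scale == "log2":
        if (reference <= 0).any() or (baseline <= 0).any() or (treated <= 0).any():
            raise RecoveryError("log2 recovery requires positive expression values")
        ref, base, trt = (np.log2(v.to_numpy(float))
                          for v in (reference, baseline, treated))
    elif scale == "linear":
        ref, base, trt = (v.to_numpy(float)
                          for v in (reference, baseline, treated))
    else:
        raise RecoveryError(f"unknown scale: {scale}")
    span = ref - base
    degenerate = np.abs(span) < degeneracy_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (trt - base) / span
    r[degenerate] = np.nan
    return pd.DataFrame({"reference": ref, "baseline": base, "treated": trt,
                         "recovery": r, "degenerate": degenerate},
                        index=reference.index)


@dataclass
class RecoveryReport:
    per_gene: pd.DataFrame
    thresholds: tuple[float, ...] = (0.25, 0.50)
    percent_at: dict[float, float] = field(default_factory=dict)
    n_genes: int = 0
    n_degenerate: int = 0

    def to_dict(self) -> dict:
        return {"n_genes": self.n_genes, "n_degenerate": self.n_degenerate,
                "percent_at": {str(t): v for t, v in self.percent_at.items()}}


def recovery_summary(per_gene: pd.DataFrame,
                     thresholds=(0.25, 0.50)) -> RecoveryReport:
    """Percentage of non-degenerate genes with recovery >= each threshold."""
    r = per_gene["recovery"]
    valid = r[~per_gene["degenerate"].astype(bool)]
    if len(valid) == 0:
        raise RecoveryError("no non-degenerate genes to summarize")
    percent = {float(t): float(100.0 * (valid >= t).mean()) for t in thresholds}
    return RecoveryReport(per_gene=per_gene, thresholds=tuple(thresholds),
                          percent_at=percent, n_genes=len(valid),
                          n_degenerate=int(per_gene["degenerate"].sum()))


def recovery_from_matrix(expr: pd.DataFrame, sheet: pd.DataFrame,
                         genes, reference: dict, baseline: dict, treated: dict,
                         scale: str = "log2",
                         thresholds=(0.25, 0.50)) -> RecoveryReport:
    """Convenience wrapper: group means from a matrix + sample sheet.

    ``reference``/``baseline``/``treated`` are sample-sheet selectors, e.g.
    ``{"passage": "P0"}``; ``genes`` restricts to a passage-dependent set.
    """
    def group_mean(selector):
        mask = np.ones(len(sheet), dtype=bool)
        for key, value in selector.items():
            mask &= (sheet[key] == value).to_numpy()
        ids = sheet.loc[mask, "sample_id"].tolist()
        if not ids:
            raise RecoveryError(f"no samples match {selector}")
        return expr.loc[genes, ids].mean(axis=1)

    per_gene = recovery_fraction(group_mean(reference), group_mean(baseline),
                                 group_mean(treated), scale=scale)
    return recovery_summary(per_gene, thresholds=thresholds)


def profile_correlation(sample_profile: pd.Series,
                        reference_profiles: pd.DataFrame,
                        gene_universe=None) -> float:
    """Pearson correlation of a sample's log2 profile with the mean reference
    profile over the expressed-gene universe. Returns NaN when either vector
    has zero variance."""
    ref_mean = reference_profiles.mean(axis=1)
    if gene_universe is not None:
        gene_universe = pd.Index(gene_universe)
        sample_profile = sample_profile.loc[gene_universe]
        ref_mean = ref_mean.loc[gene_universe]
    if len(sample_profile) < 3:
        raise RecoveryError("profile correlation needs at least three genes")
    x = sample_profile.to_numpy(float)
    y = ref_mean.to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def percent_of_max(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to a percentage of its own maximum (heatmap scaling).

    Rows whose maximum is zero cannot be scaled and come back as NaN.
    """
    x = matrix.to_numpy(float)
    row_max = x.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * x / row_max[:, None]
    out[row_max <= 0] = np.nan
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
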