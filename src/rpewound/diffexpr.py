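"""Donor-consistent fold-change differential expression and its empirical null.

The caller declares a gene differentially expressed between two conditions
at a time point only when every donor's own (intra-donor) fold change is at
least ``min_each`` in the same direction AND the mean fold change across
donors is at least ``min_mean`` (boundaries inclusive; defaults 1.5 and
2.0). A gene is passage-dependent if it is called at one or more time
points. The expected-by-chance call count is estimated empirically by
applying the same criterion to comparisons between donors within a single
condition, where no real effect exists but donor-to-donor variation does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_EACH_DEFAULT = 1.5
MIN_MEAN_DEFAULT = 2.0


class DiffExprError(ValueError):
    pass


def donor_fold_call(expr_a, expr_b, min_each: float = MIN_EACH_DEFAULT,
                    min_mean: float = MIN_MEAN_DEFAULT,
                    mean_kind: str = "arithmetic"):
    """Call one gene from matched per-donor values in conditions a and b.

    Per-donor ratios ``r_d = b_d / a_d`` must all lie on the same side of 1;
    the direction-consistent magnitude is ``r_d`` (all > 1, up) or ``1/r_d``
    (all < 1, down). The call is up/down iff every magnitude >= ``min_each``
    and their mean >= ``min_mean``; otherwise none.

    Returns ``(call, ratios, mean_fold)`` where ``mean_fold`` is the mean of
    the direction-consistent magnitudes (NaN when direction is inconsistent).
    """
    a = np.asarray(expr_a, float)
    b = np.asarray(expr_b, float)
    if a.shape != b.shape:
        raise DiffExprError("conditions must have matched donors")
    if (a <= 0).any() or (b <= 0).any():
        raise DiffExprError("expression values must be positive (floor upstream)")
    r = b / a
    calls, folds = _vector_calls(r[None, :], min_each, min_mean, mean_kind)
    return calls[0], r, folds[0]


def _vector_calls(ratios: np.ndarray, min_each: float, min_mean: float,
                  mean_kind: str = "arithmetic"):
    """Vectorized criterion over a genes x donors ratio matrix.

    Returns (calls: array of 'up'/'down'/'none', mean_fold: array, NaN where
    direction-inconsistent).
    """
    all_up = (ratios > 1.0).all(axis=1)
    all_down = (ratios < 1.0).all(axis=1)
    mag = np.where(all_down[:, None], 1.0 / ratios, ratios)
    consistent = all_up | all_down
    if mean_kind == "arithmetic":
        mean_fold = mag.mean(axis=1)
    elif mean_kind == "geometric":
        mean_fold = np.exp(np.log(mag).mean(axis=1))
    else:
        raise DiffExprError(f"unknown mean_kind: {mean_kind}")
    mean_fold = np.where(consistent, mean_fold, np.nan)
    passes = consistent & (mag >= min_each).all(axis=1) & (mean_fold >= min_mean)
    calls = np.where(passes & all_up, "up",
                     np.where(passes & all_down, "down", "none"))
    return calls, mean_fold


def call_genes(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
               min_each: float = MIN_EACH_DEFAULT,
               min_mean: float = MIN_MEAN_DEFAULT,
               mean_kind: str = "arithmetic") -> pd.DataFrame:
    """Apply the donor-consistency criterion to every gene.

    ``expr_a`` and ``expr_b`` are genes x donors matrices with matching rows
    and donor-matched columns. Returns a frame with per-donor folds, mean
    fold and the call.
    """
    if not expr_a.index.equals(expr_b.index):
        raise DiffExprError("gene lists of the two conditions differ")
    if expr_a.shape[1] != expr_b.shape[1]:
        raise DiffExprError("conditions must have the same number of donors")
    a = expr_a.to_numpy(float)
    b = expr_b.to_numpy(float)
    if (a <= 0).any() or (b <= 0).any():
        raise DiffExprError("expression values must be positive (floor upstream)")
    ratios = b / a
    calls, mean_fold = _vector_calls(ratios, min_each, min_mean, mean_kind)
    out = pd.DataFrame(index=expr_a.index)
    for d in range(ratios.shape[1]):
        out[f"fold_donor{d + 1}"] = ratios[:, d]
    out["mean_fold"] = mean_fold
    out["call"] = calls
    return out


def _condition_matrix(expr: pd.DataFrame, sheet: pd.DataFrame,
                      selector: dict) -> pd.DataFrame:
    """Genes x donors matrix for the samples matching ``selector``,
    columns ordered by donor."""
    mask = np.ones(len(sheet), dtype=bool)
    for key, value in selector.items():
        mask &= (sheet[key] == value).to_numpy()
    sub = sheet[mask].sort_values("donor")
    if sub["donor"].duplicated().any():
        raise DiffExprError(f"multiple samples per donor for {selector}")
    mat = expr[sub["sample_id"].tolist()]
    mat.columns = sub["donor"].tolist()
    return mat


@dataclass
class DECallTable:
    """Per-gene, per-time-point calls plus the union-over-time summary."""

    per_time: dict[int, pd.DataFrame]
    summary: pd.DataFrame  # gene x [overall_call in {up, down, none, ambiguous}]
    min_each: float = MIN_EACH_DEFAULT
    min_mean: float = MIN_MEAN_DEFAULT

    @property
    def up_genes(self) -> pd.Index:
        return self.summary.index[self.summary["overall_call"] == "up"]

    @property
    def down_genes(self) -> pd.Index:
        return self.summary.index[self.summary["overall_call"] == "down"]

    @property
    def ambiguous_genes(self) -> pd.Index:
        return self.summary.index[self.summary["overall_call"] == "ambiguous"]

    def to_frame(self) -> pd.DataFrame:
        """Flat per-gene table: per-time folds/calls plus the overall call."""
        pieces = []
        for day, tab in sorted(self.per_time.items()):
            pieces.append(tab.add_prefix(f"day{day}_"))
        out = pd.concat(pieces + [self.summary], axis=1)
        out.index.name = "gene"
        return out


def de_call_table(expr: pd.DataFrame, sheet: pd.DataFrame,
                  condition_col: str = "passage", ref: str = "P0",
                  alt: str = "P5", within: str = "day",
                  min_each: float = MIN_EACH_DEFAULT,
                  min_mean: float = MIN_MEAN_DEFAULT,
                  mean_kind: str = "arithmetic",
                  extra_selector: dict | None = None) -> DECallTable:
    """Call DE per time point (``within`` level) and take the union over time.

    Genes called up at one time point and down at another are flagged
    ``ambiguous`` and belong to neither set.
    """
    levels = sorted(sheet.loc[sheet[condition_col].isin([ref, alt]), within].unique())
    per_time = {}
    for level in levels:
        sel_ref = {condition_col: ref, within: level, **(extra_selector or {})}
        sel_alt = {condition_col: alt, within: level, **(extra_selector or {})}
        a = _condition_matrix(expr, sheet, sel_ref)
        b = _condition_matrix(expr, sheet, sel_alt)
        per_time[level] = call_genes(a, b, min_each, min_mean, mean_kind)
    calls = pd.DataFrame({lvl: t["call"] for lvl, t in per_time.items()})
    any_up = (calls == "up").any(axis=1)
    any_down = (calls == "down").any(axis=1)
    overall = np.where(any_up & any_down, "ambiguous",
                       np.where(any_up, "up",
                                np.where(any_down, "down", "none")))
    summary = pd.DataFrame({"overall_call": overall}, index=calls.index)
    return DECallTable(per_time=per_time, summary=summary,
                       min_each=min_each, min_mean=min_mean)


def passage_dependent_genes(table: DECallTable) -> tuple[pd.Index, pd.Index]:
    """Up and down gene sets from the union over time points (ambiguous
    bidirectional genes excluded from both)."""
    return table.up_genes, table.down_genes


@dataclass
class NullEstimate:
    """Expected-by-chance call count from inter-donor comparisons."""

    condition: str
    count: int
    n_genes: int
    comparisons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"condition": self.condition, "count": self.count,
                "n_genes": self.n_genes,
                "comparisons": [list(c) for c in self.comparisons]}


def empirical_null_counts(expr: pd.DataFrame, sheet: pd.DataFrame,
                          condition: dict,
                          min_each: float = MIN_EACH_DEFAULT,
                          min_mean: float = MIN_MEAN_DEFAULT,
                          mean_kind: str = "arithmetic",
                          pairing: str = "pairs") -> NullEstimate:
    """Apply the DE criterion to inter-donor comparisons within one condition.

    With donors (A, B, C, ...) the default pairing forms every unordered
    donor pair with a consistent orientation — (A,B), (A,C), (B,C) for three
    donors — and treats them as pseudo intra-donor comparisons:
    pseudo-condition "a" holds the first member of each pair and "b" the
    second. Genes called in either direction are counted; since no true
    condition contrast exists, the count estimates the criterion's
    false-call rate under the observed donor and residual variation.

    The cyclic pairing (A,B), (B,C), (C,A) is available as
    ``pairing="cyclic"`` but is degenerate for this criterion: its log
    folds sum to zero by construction, so a same-direction call can never
    occur and the estimate is identically 0.
    """
    import itertools

    mat = _condition_matrix(expr, sheet, condition)
    donors = list(mat.columns)
    if len(donors) < 2:
        raise DiffExprError("empirical null needs at least two donors")
    if pairing == "pairs":
        pairs = list(itertools.combinations(donors, 2))
    elif pairing == "cyclic":
        pairs = [(donors[i], donors[(i + 1) % len(donors)])
                 for i in range(len(donors))]
    else:
        raise DiffExprError(f"unknown pairing: {pairing}")
    a = mat[[p[0] for p in pairs]]
    b = mat[[p[1] for p in pairs]]
    b.columns = a.columns = range(len(pairs))
    table = call_genes(a, b, min_each, min_mean, mean_kind)
    label = ",".join(f"{k}={v}" for k, v in condition.items())
    return NullEstimate(condition=label,
                        count=int((table["call"] != "none").sum()),
                        n_genes=len(mat), comparisons=pairs)
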