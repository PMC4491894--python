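"""Count-matrix normalization: TMM scaling factors, CPM, and expression filter.

TMM (trimmed mean of M-values) computes, for each sample against a
reference sample, the precision-weighted mean of log2 expression ratios
after trimming the most extreme ratios (M) and abundances (A); the
resulting per-sample factors multiply the library sizes before
counts-per-million scaling. Genes are called expressed if they reach
``min_rpm`` reads per million in at least ``min_samples`` samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class CountMatrixError(ValueError):
    pass


def _validate_counts(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy(float)
    if (x < 0).any():
        raise CountMatrixError("counts must be non-negative")
    if not np.allclose(x, np.round(x)):
        raise CountMatrixError("counts must be integral")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise CountMatrixError(f"samples with zero total counts: {bad}")
    return x


def _choose_reference(x: np.ndarray) -> int:
    """Sample whose 75th-percentile scaled count is closest to the mean one."""
    lib = x.sum(axis=0)
    uq = np.array([np.quantile(x[:, j] / lib[j], 0.75)
                   for j in range(x.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(counts: pd.DataFrame, reference_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    For each sample k versus the reference r, genes with a zero count in
    either sample are excluded; with library sizes N and counts Y,

        M_g = log2( (Y_gk/N_k) / (Y_gr/N_r) )
        A_g = 0.5 * log2( (Y_gk/N_k) * (Y_gr/N_r) )
        v_g = (N_k - Y_gk)/(N_k Y_gk) + (N_r - Y_gr)/(N_r Y_gr)

    the genes in the upper/lower ``trim_m`` tail of M or ``trim_a`` tail of
    A are dropped, and the factor is the precision-weighted mean
    ``2**(sum(M/v)/sum(1/v))`` over the rest, ``v`` being the delta-method
    binomial variance of M.
    """
    x = _validate_counts(counts)
    n_genes, n_samples = x.shape
    if n_samples < 2:
        raise CountMatrixError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    if reference_sample is None:
        ref = _choose_reference(x)
    else:
        ref = counts.columns.get_loc(reference_sample)
    yr, nr = x[:, ref], lib[ref]
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        yk, nk = x[:, j], lib[j]
        ok = (yk > 0) & (yr > 0)
        if ok.sum() == 0:
            raise CountMatrixError(
                f"no genes shared between sample {counts.columns[j]} and reference")
        pk, pr = yk[ok] / nk, yr[ok] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        # binomial delta-method variance of M; precision weight is 1/v
        v = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        w = 1.0 / v
        # doubly trimmed: a gene survives only if inside both rank windows
        # (1-based average ranks; window [floor(n*trim)+1, n-floor(n*trim)])
        from scipy.stats import rankdata
        n = len(m)
        rank_m = rankdata(m, method="average")
        rank_a = rankdata(a, method="average")
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = ((rank_m >= lo_m) & (rank_m <= hi_m)
                & (rank_a >= lo_a) & (rank_a <= hi_a))
        if keep.sum() == 0 or w[keep].sum() <= 0:
            factors[j] = 1.0
        else:
            factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm_normalize(counts: pd.DataFrame, factors: pd.Series | None = None,
                  floor: float = 0.0) -> pd.DataFrame:
    """Counts per million on TMM-adjusted library sizes:
    ``RPM = count / (library_size * factor) * 1e6``.

    ``floor`` > 0 clips the result from below (zero counts give zero RPM,
    which downstream ratio-based statistics cannot consume)."""
    x = _validate_counts(counts)
    lib = x.sum(axis=0)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    f = factors.reindex(counts.columns).to_numpy(float)
    rpm = x / (lib * f) * 1e6
    if floor > 0:
        rpm = np.clip(rpm, floor, None)
    return pd.DataFrame(rpm, index=counts.index, columns=counts.columns)


def expression_filter(rpm: pd.DataFrame, min_rpm: float = 1.0,
                      min_samples: int = 3) -> pd.Index:
    """Genes with RPM >= ``min_rpm`` in at least ``min_samples`` samples
    (both boundaries inclusive)."""
    hits = (rpm >= min_rpm).sum(axis=1)
    return rpm.index[hits >= min_samples]
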