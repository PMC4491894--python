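"""Two-color microarray preprocessing: probe intensities to a gene-level matrix.

The fixed stage order is background subtraction, (optional) lowess dye
correction, replicate-probe averaging, quantile normalization, detection
filtering and probe-to-gene collapsing. Net intensities are floored at 1.0
so downstream log transforms and fold changes stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

NET_FLOOR = 1.0


class PreprocessError(ValueError):
    pass


def subtract_background(raw: pd.DataFrame, annotation: pd.DataFrame,
                        floor: float = NET_FLOOR
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract each sample's mean negative-control intensity from every probe.

    Returns the floored net matrix and the per-sample background estimate
    (the negative-control mean), which the detection filter reuses.
    """
    annotation = annotation.set_index("probe_id").loc[raw.index]
    nc = annotation["is_negative_control"].astype(bool).to_numpy()
    if nc.sum() == 0:
        raise PreprocessError("no negative-control probes: cannot estimate background")
    background = raw.loc[nc].mean(axis=0)
    net = raw.sub(background, axis=1).clip(lower=floor)
    return net, background


def lowess_normalize(channel1: pd.DataFrame, channel2: pd.DataFrame,
                     frac: float = 0.3, it: int = 3
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove intensity-dependent dye bias by lowess on M-A coordinates.

    M = log2(channel2/channel1), A = mean log2 intensity. A locally weighted
    regression of M on A is subtracted per sample and the two channels are
    reconstructed from the corrected M and the unchanged A, so after
    correction the lowess trend of M on A is ~0 everywhere.
    """
    if not channel1.index.equals(channel2.index) or \
            not channel1.columns.equals(channel2.columns):
        raise PreprocessError("channel matrices must share probes and samples")
    for name, ch in (("channel1", channel1), ("channel2", channel2)):
        bad = ch.index[(ch <= 0).any(axis=1)]
        if len(bad):
            raise PreprocessError(
                f"non-positive intensities in {name} for probes "
                f"{bad[:5].tolist()}{'...' if len(bad) > 5 else ''}")
    l1 = np.log2(channel1.to_numpy(float))
    l2 = np.log2(channel2.to_numpy(float))
    m = l2 - l1
    a = 0.5 * (l1 + l2)
    m_corr = np.empty_like(m)
    for j in range(m.shape[1]):
        fit = _sm_lowess(m[:, j], a[:, j], frac=frac, it=it,
                         return_sorted=False)
        m_corr[:, j] = m[:, j] - fit
    out1 = pd.DataFrame(2.0 ** (a - m_corr / 2.0), index=channel1.index,
                        columns=channel1.columns)
    out2 = pd.DataFrame(2.0 ** (a + m_corr / 2.0), index=channel2.index,
                        columns=channel2.columns)
    return out1, out2


def average_replicate_probes(net: pd.DataFrame, annotation: pd.DataFrame
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse each replicate-probe group to its arithmetic per-sample mean.

    The collapsed row keeps the lexicographically smallest member probe id;
    non-replicated probes pass through unchanged. Returns the reduced matrix
    and a correspondingly reduced annotation.
    """
    annotation = (annotation.set_index("probe_id").loc[net.index]
                  .rename_axis("probe_id").reset_index())
    group = annotation["replicate_group"].fillna("").astype(str)
    in_group = group != ""
    passthrough = net.loc[~in_group.to_numpy()]
    pieces = [passthrough]
    annot_pieces = [annotation.loc[~in_group.to_numpy()]]
    if in_group.any():
        sub = net.loc[in_group.to_numpy()].copy()
        sub_annot = annotation.loc[in_group.to_numpy()]
        means = sub.groupby(sub_annot["replicate_group"].to_numpy()).mean()
        rep_ids = sub_annot.groupby("replicate_group")["probe_id"].min()
        means.index = rep_ids.loc[means.index].to_numpy()
        means.index.name = net.index.name
        rep_annot = (sub_annot.sort_values("probe_id")
                     .groupby("replicate_group", as_index=False).first())
        pieces.append(means)
        annot_pieces.append(rep_annot[annotation.columns])
    out = pd.concat(pieces)
    out_annot = pd.concat(annot_pieces, ignore_index=True)
    return out, out_annot


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns reference distribution.

    Ranks within each column are preserved; tied values receive the mean of
    the reference values their ranks span, which makes the transform
    idempotent.
    """
    x = matrix.to_numpy(float)
    if not np.isfinite(x).all():
        raise PreprocessError("quantile normalization requires finite values")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[np.minimum(hi, n - 1)])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class DetectionResult:
    kept: pd.Index
    flags: pd.DataFrame  # probe x sample booleans: net >= multiplier * background


def detection_filter(net: pd.DataFrame, background: pd.Series,
                     multiplier: float = 2.0) -> DetectionResult:
    """Keep probes whose net intensity reaches ``multiplier`` x background
    in at least one sample (boundary inclusive); probes below it in every
    sample are discarded. Per-sample detection flags are retained to build
    the expressed-gene universe."""
    background = background.reindex(net.columns)
    flags = net.ge(multiplier * background, axis=1)
    kept = net.index[flags.any(axis=1)]
    return DetectionResult(kept=kept, flags=flags)


def collapse_probes_to_genes(net: pd.DataFrame, annotation: pd.DataFrame
                             ) -> pd.DataFrame:
    """One probe per gene: pick the probe with the highest mean intensity.

    Probes without a gene symbol (including negative controls) are dropped.
    Ties on mean intensity break to the lexicographically smallest probe id.
    Output rows are unique gene symbols.
    """
    annotation = annotation.set_index("probe_id").loc[net.index]
    symbol = annotation["gene_symbol"].fillna("").astype(str)
    keep = symbol != ""
    sub = net.loc[keep.to_numpy()]
    symbols = symbol[keep.to_numpy()]
    means = sub.mean(axis=1)
    chooser = pd.DataFrame({"gene": symbols.to_numpy(), "mean": means.to_numpy(),
                            "probe_id": sub.index})
    chooser = chooser.sort_values(["gene", "mean", "probe_id"],
                                  ascending=[True, False, True])
    best = chooser.groupby("gene", sort=True).first()
    out = sub.loc[best["probe_id"].to_numpy()]
    out.index = best.index
    out.index.name = "gene"
    return out


def preprocess_array(raw: pd.DataFrame, annotation: pd.DataFrame,
                     channel2: pd.DataFrame | None = None,
                     detection_multiplier: float = 2.0,
                     lowess_frac: float = 0.3) -> dict:
    """Run the full probe-to-gene pipeline in the fixed stage order.

    With a second channel, both channels are background-subtracted, lowess
    dye correction is applied, and the corrected sample channel (``raw``)
    is carried forward. Returns a dict with the gene-level matrix, the
    detection flags, the per-sample background and intermediate shapes.
    """
    net, background = subtract_background(raw, annotation)
    if channel2 is not None:
        net2, _ = subtract_background(channel2, annotation)
        net, _ = lowess_normalize(net, net2, frac=lowess_frac)
    net, annotation = average_replicate_probes(net, annotation)
    norm = quantile_normalize(net)
    detection = detection_filter(norm, background,
                                 multiplier=detection_multiplier)
    kept = norm.loc[detection.kept]
    kept_annot = annotation[annotation["probe_id"].isin(detection.kept)]
    genes = collapse_probes_to_genes(kept, kept_annot)
    return {
        "gene_matrix": genes,
        "detection_flags": detection.flags,
        "background": background,
        "n_probes_in": len(raw),
        "n_probes_detected": len(detection.kept),
        "n_genes": len(genes),
    }
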