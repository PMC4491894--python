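"""RT-qPCR relative quantification with housekeeping-gene normalization.

Assuming 100 % PCR efficiency the template quantity is ``Q = 2**(-Ct)``.
Each gene's quantity is divided by the geometric mean of the quantities of
three housekeeping genes measured in the same sample — equivalently
``2**(mean(Ct_housekeeping) - Ct_gene)`` — which cancels any per-sample Ct
offset (loading, cDNA input). Duplicate wells are averaged on the Ct scale
before quantification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_HOUSEKEEPING = ("RPL15", "NDUFA11", "UBB")


class QpcrError(ValueError):
    pass


def average_replicate_wells(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over replicate wells per (gene, sample)."""
    if (ct["ct"] <= 0).any() or not np.isfinite(ct["ct"]).all():
        raise QpcrError("Ct values must be finite and > 0")
    return ct.groupby(["gene", "sample"], as_index=False)["ct"].mean()


def relative_expression(ct: pd.DataFrame,
                        housekeeping=DEFAULT_HOUSEKEEPING) -> pd.DataFrame:
    """Housekeeping-normalized expression, genes x samples.

    ``ct`` is a tidy table with columns gene, sample, ct (and optionally
    replicate). Every housekeeping gene must be measured in every sample.
    """
    housekeeping = list(housekeeping)
    averaged = average_replicate_wells(ct)
    wide = averaged.pivot(index="gene", columns="sample", values="ct")
    for sample in wide.columns:
        for hk in housekeeping:
            if hk not in wide.index or pd.isna(wide.loc[hk, sample]):
                raise QpcrError(
                    f"housekeeping gene {hk} missing in sample {sample}")
    hk_mean = wide.loc[housekeeping].mean(axis=0)
    rel = 2.0 ** (hk_mean - wide)
    rel.index.name = "gene"
    return rel
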