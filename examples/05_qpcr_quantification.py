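"""Relative RT-qPCR quantification against three housekeeping genes.

Quantities assume 100 % PCR efficiency (one doubling per cycle), so a gene
with Ct three cycles below the housekeeping mean is 2**3 = 8-fold enriched
relative to the housekeeping geometric mean.
"""

import pandas as pd

from rpewound import percent_of_max, relative_expression

rows = []
for sample, shift in (("P0", 0.0), ("P5", 0.0), ("P5_A83", 0.0)):
    # duplicate wells per gene, housekeeping genes constant across samples
    for rep in (1, 2):
        rows += [("RPE65", sample, rep, {"P0": 21.0, "P5": 26.0,
                                         "P5_A83": 22.0}[sample] + 0.1 * rep),
                 ("ACTA2", sample, rep, {"P0": 27.0, "P5": 23.0,
                                         "P5_A83": 26.5}[sample] + 0.1 * rep),
                 ("RPL15", sample, rep, 22.0), ("NDUFA11", sample, rep, 23.0),
                 ("UBB", sample, rep, 24.0)]
ct = pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])

rel = relative_expression(ct)
print("relative expression (housekeeping-normalized):")
print(rel.loc[["RPE65", "ACTA2"]].round(3))

print("\nas percent of each gene's maximum (heatmap scaling):")
print(percent_of_max(rel.loc[["RPE65", "ACTA2"]]).round(1))
# RPE65 (an RPE marker) collapses in P5 and is restored by the inhibitor;
# ACTA2 (a mesenchymal marker) shows the mirror image
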