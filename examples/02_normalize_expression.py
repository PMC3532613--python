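"""Housekeeping-gene normalization of Ct values, by hand.

Builds a one-sample panel where the five housekeeping genes average
30.0 cycles and three target genes sit at known offsets, then shows the
delta-Ct arithmetic: value = 100 * 2**(mean HK Ct - gene Ct), so one
cycle fewer doubles the value.
"""

import pandas as pd

from oncorule.preprocess import CtPanel, normalize_expression
from oncorule.rules import HOUSEKEEPING_GENES

cts = {g: 30.0 for g in HOUSEKEEPING_GENES}
cts.update({"GENE_EQ": 30.0, "GENE_LOW": 33.0, "GENE_HIGH": 27.0})

ct = pd.DataFrame({
    "sample_id": ["s1"] * len(cts),
    "gene_id": list(cts),
    "ct_rep1": list(cts.values()),
    "ct_rep2": list(cts.values()),
})
meta = pd.DataFrame({"rna_conc_ng_ul": [45.0], "a260_280": [1.96]},
                    index=pd.Index(["s1"], name="sample_id"))
expr = normalize_expression(CtPanel(ct=ct, meta=meta))

for gene in ("GENE_EQ", "GENE_LOW", "GENE_HIGH"):
    ct_val = cts[gene]
    print(f"{gene}: Ct {ct_val:5.1f}  ->  expression {expr.values.loc['s1', gene]:7.1f}")

# GENE_EQ matches the housekeeping mean (delta-Ct 0) and lands at 100;
# GENE_LOW needs 3 more cycles (8-fold less transcript, value 12.5);
# GENE_HIGH needs 3 fewer (8-fold more, value 800).
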