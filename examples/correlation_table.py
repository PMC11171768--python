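"""Spearman correlogram table over per-dish germination indices.

Builds a per-replicate index table from a simulated germination screen
(each dish scored against the control-group means) and computes all
pairwise Spearman correlations with t-approximation p-values — the
numeric content of a germination-index correlogram.
"""

import pandas as pd

from ecotoxscreen import compute_group_indices, correlation_matrix
from ecotoxscreen.simulate import GerminationSimConfig, simulate_germination

reps = simulate_germination(GerminationSimConfig(seed=21, emax=0.6, ec50=500.0))
control = [r for r in reps if r.concentration is None]

rows = []
for rep in reps:
    idx = compute_group_indices([rep], control, mode="pooled")
    rows.append({k: v.mean for k, v in idx.values.items()})
frame = pd.DataFrame(rows)[["Eg", "G", "RL", "SL", "RRG", "RSG", "GI", "VI", "PI"]]

table = correlation_matrix(frame)
print(table.to_string(index=False, float_format="%.4f"))

# rho2 is the squared rank correlation often printed in correlograms;
# strong positive pairs (e.g. GI with RRG) reflect indices sharing the
# same underlying germination/growth signal.
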