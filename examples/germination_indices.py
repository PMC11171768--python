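"""Germination phytotoxicity indices on a simulated wheat screen.

Simulates a Petri-dish germination test (5 dishes x 10 seeds per
condition, Hill-type inhibition of germination and seedling growth),
applies the <3-germinated exclusion rule and reports the nine indices
per condition as mean ± SD against the water control.
"""

from ecotoxscreen import compute_group_indices, exclude_sparse_groups
from ecotoxscreen.simulate import GerminationSimConfig, simulate_germination

reps = simulate_germination(GerminationSimConfig(seed=11, emax=0.5, ec50=600.0))
retained, excluded = exclude_sparse_groups(reps, min_germinated=3)
for _, reason in excluded:
    print(f"excluded dish: {reason}")

control = [r for r in retained if r.concentration is None]
conditions = sorted({r.condition for r in retained}, key=lambda c: (c != "control", c))
for name in conditions:
    group = [r for r in retained if r.condition == name]
    idx = compute_group_indices(group, control)
    cells = ", ".join(
        f"{k}={v.mean:.1f}±{v.sd:.1f}" for k, v in idx.values.items()
    )
    print(f"{name:>14}: {cells}")

# RRG/RSG/GI/PI read as percent of the control (100 = no effect, lower =
# inhibition); the control row is the reference, so its relative indices
# are exactly 100 and GI equals G.
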