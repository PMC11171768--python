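"""MTS cell-viability percentages and IC50 by linear regression.

Simulates a 96-well MTS plate (five extract concentrations in
triplicate plus untreated controls), converts well absorbances to
percent viability of the control mean, fits viability on concentration
and inverts the line at 50% for the IC50.
"""

import numpy as np

from ecotoxscreen import assay_summary, viability_pct
from ecotoxscreen.simulate import ViabilitySimConfig, simulate_viability

records = simulate_viability(ViabilitySimConfig(seed=3, cell_line="HepG2"))
control_mean = float(np.mean([r.absorbance for r in records if r.is_control]))
treated = [r for r in records if not r.is_control]

summary = assay_summary(
    [r.concentration for r in treated],
    [viability_pct(r.absorbance, control_mean) for r in treated],
    response_label="percent viability",
)
print(summary.table.to_string(index=False, float_format="%.2f"))
flag = " (extrapolated: well beyond the tested 10-500 µg/mL)" if summary.extrapolated else ""
print(f"IC50 = {summary.inverted_concentration:.1f} µg/mL{flag}")

# Viability near or above 100% across the tested range with an IC50 far
# outside it indicates biocompatibility rather than cytotoxicity.
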