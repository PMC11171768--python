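"""Probit LC50 from a brine-shrimp lethality dilution series.

Inputs are the per-dose mean mortality percentages of an acute screen
(four extract concentrations, 10 larvae per vessel) at two reading
times.  The analysis replaces 0%/100% mortalities (Miller-Tainter),
transforms to probits, regresses probit on log10 dose and solves the
line at probit 5 for the LC50, then classifies it on Clarkson's scale.
"""

from ecotoxscreen import classify_clarkson, fit_probit_from_percentages

doses = (250.0, 500.0, 1000.0, 2000.0)  # µg/mL
readings = {
    "24 h": (0.0, 0.0, 37.0, 100.0),    # mean % mortality per dose
    "48 h": (17.0, 57.0, 100.0, 100.0),
}

for label, mortality in readings.items():
    fit = fit_probit_from_percentages(doses, mortality, n_per_group=10)
    print(f"{label}: probit line Y = {fit.slope:.4f}X {fit.intercept:+.4f}")
    print(f"      r² = {fit.r_squared:.4f}, p = {fit.p_value:.4f}")
    print(
        f"      LC50 = {fit.lc50:.2f} µg/mL (log10 = {fit.log_lc50:.4f}), "
        f"Clarkson toxicity: {classify_clarkson(fit.lc50)}"
    )

# The slope is the probit increase per tenfold dose increase (steeper =
# sharper tolerance distribution); LC50 is the dose killing half the
# larvae.  Falling LC50 from 24 h to 48 h means toxicity grows with
# exposure time.
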