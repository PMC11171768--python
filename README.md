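# ecotoxscreen

Statistics for the small-scale toxicity screening battery commonly
applied to plant extracts and other natural products: seed-germination
phytotoxicity tests, the brine-shrimp (*Artemia salina*) lethality
assay, erythrocyte hemolysis, carboxyfluorescein (CF) leakage from
liposomes, and MTS cell-viability plates. It is written for
ecotoxicologists and natural-product researchers who have per-replicate
assay tables (CSV) and want the classical desk analyses — germination
indices, corrected-probit LC50, HC50/IC50 by line inversion, Spearman
correlograms — as tested, scriptable functions rather than spreadsheet
formulas.

## What it computes

**Probit LC50.** For dose groups with mortality proportion *p* at
concentration *c*, extreme values are first replaced following Miller
and Tainter (0% → 0.25/*n*, 100% → (*n*−0.25)/*n*; Abbott's correction
for background control mortality is applied first when needed), then
transformed to probability units

&nbsp;&nbsp;&nbsp;&nbsp;Y = 5 + Φ⁻¹(p),

rounded to two decimals as when read from a printed probit table.
Ordinary least squares of Y on X = log₁₀ c gives the line Y = bX + a;
the median lethal concentration is LC50 = 10^((5 − a)/b), classified on
Clarkson's scale (≤0.1 mg/mL highly toxic … >1 mg/mL non-toxic).

**Germination indices.** From per-dish counts and seedling lengths:
germinative energy Eg and germination rate G (percent germinated at the
energy-day and final readings), mean root/shoot lengths RL and SL,
relative root growth RRG = 100·RL/RL₀, relative seed germination
RSG = 100·g/g₀, germination index GI = G·RRG/100, vigor index
VI = G·(RL + SL), and aerial influence index
PI = 100·(G·SL)/(G₀·SL₀), with the subscript 0 denoting the water
control. Dishes with fewer than three germinated seeds are excluded.

**Membrane endpoints.** Hemolysis % = 100·(A − A₀)/(A₁₀₀ − A₀), CF
release % = 100·(F_t − F₀)/(F_T − F₀), viability % relative to
untreated control wells; each assay's percent-vs-concentration line is
fitted and inverted at 50% for HC50/IC50 with extrapolation flags.

**Correlations.** Spearman rank correlations (midranks for ties,
t-approximation p-values, exact permutation p for n ≤ 8) over any
replicate-by-index table.

Seeded generators in `ecotoxscreen.simulate` emulate every assay's
statistical structure, so the full pipeline runs and parameter-recovery
checks are possible without external data.

## Worked example

```python
from ecotoxscreen import classify_clarkson, fit_probit_from_percentages

doses = (250.0, 500.0, 1000.0, 2000.0)            # µg/mL
mortality_24h = (0.0, 0.0, 37.0, 100.0)           # mean % per dose, n = 10
fit = fit_probit_from_percentages(doses, mortality_24h, n_per_group=10)
print(f"Y = {fit.slope:.4f}X {fit.intercept:+.4f}, r² = {fit.r_squared:.4f}")
print(f"LC50 = {fit.lc50:.2f} µg/mL -> {classify_clarkson(fit.lc50)}")
```

prints

```
Y = 4.4481X -8.2472, r² = 0.8684
LC50 = 951.03 µg/mL -> low
```

The slope (probits per tenfold dose increase) describes how sharply
mortality rises with dose; LC50 is the concentration killing half the
organisms; "low" is its Clarkson toxicity class (0.5–1 mg/mL). The
`examples/` directory holds one short script per capability
(germination indices, HC50, IC50, leakage endpoint, correlograms, the
full CSV-to-report pipeline), and the `ecotoxscreen` console script
exposes the same stages as subcommands (`germ`, `lc50`, `hemolysis`,
`leakage`, `viability`, `correlate`, `simulate`, `report`).

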