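# Methods

This note records the statistical models implemented in `ecotoxscreen`,
the conventions and defaults chosen where the classical desk procedures
leave room, and what the synthetic-data generators do and do not
emulate.

## Probit dose–response analysis

The brine-shrimp lethality module implements the classical
table-and-regression probit workflow rather than Finney's iteratively
reweighted maximum-likelihood fit, because that is the procedure used
by the desk analyses this package targets and the two differ
appreciably only at extreme mortalities or very unbalanced designs.

The steps, in order:

1. **Mortality percent** per dose group, either from cumulative counts
   (replicate vessels at the same dose are pooled: Σdead/Σtotal) or
   supplied directly as per-dose mean percentages
   (`fit_probit_from_percentages`) together with the per-vessel group
   size *n* — the form in which screening papers tabulate the data.
2. **Abbott's correction** 100·(T − C)/(100 − C) is applied only when
   control mortality C > 0, before any other transform, and is clamped
   below at zero. Every skip/application is logged so a report's
   narrative ("no correction required") is reproducible from the log.
3. **Miller–Tainter replacement** of the extremes: 0% → 100·(0.25/n),
   100% → 100·(n − 0.25)/n. With n = 10 these are 2.5% and 97.5%,
   whose probits round to 3.04 and 6.96. The constants are the standard
   ones for this correction; interior values pass through untouched.
4. **Probit transform** Y = 5 + Φ⁻¹(p), *rounded to two decimals by
   default* (`probit_round=2`). The rounding reproduces the historical
   practice of reading probits off a printed table and measurably moves
   the fitted slope (4th decimal); it is configurable and `None`
   disables it. Analyses of simulated data in this package use
   `probit_round=None`.
5. **OLS regression** of the probit on the *full-precision* log₁₀
   concentration (not a rounded "concentration log" column — using
   rounded logs shifts the slope by ~0.1%). Implemented with
   `scipy.stats.linregress`; the p-value is the two-sided t test on the
   correlation with n − 2 df. The slope has units probit per
   log₁₀(µg/mL).
6. **LC50** = 10^((5 − a)/b). A non-positive slope yields NaN with a
   non-monotone-response warning rather than a spurious concentration.
   `se_log_lc50` gives the Miller–Tainter-style approximate error
   (log LC84 − log LC16)/√(2n); when labelled replicate vessels exist,
   `lc50_by_replicate` additionally reports the per-vessel LC50 mean ±
   SD, which is how a "± value" on a published LC50 is usually meant.
7. **Clarkson classification** with upper-inclusive bounds:
   (0, 100] µg/mL high, (100, 500] medium, (500, 1000] low,
   above 1000 non-toxic. The boundary convention (1000 → "low") is a
   package choice; the published criterion states the ranges without
   resolving the endpoints.

Cumulative mortality series are validated to be non-decreasing in time;
violations raise instead of being repaired, since they indicate
recording errors.

## Germination indices

Nine indices per condition group, always relative to the water control:
Eg, G (count-based percents), RL, SL (cm), RRG, RSG, GI = G·RRG/100,
VI = G·(RL + SL), PI = 100·(G·SL)sample/(G·SL)control.

Conventions that required a decision:

- **Scaling of GI and PI.** GI is scaled so a group identical to its
  control has GI = G (RRG = 100 contributes a factor of one), and PI is
  the ratio of G·SL products. Both conventions are validated by the
  internal-consistency requirement that every control column reads
  RRG = RSG = PI = 100 and GI = G.
- **Control against itself.** When a group *is* the control, its
  relative indices are fixed at 100 per dish (and GI = G per dish)
  rather than recomputed per dish against the control mean. The
  alternative yields mean 100 but non-zero SD, which contradicts the
  "100.00 ± 0.00" a control column must read: the control is the
  reference, not an estimate of it.
- **Two computation modes.** `per_replicate` (default) computes each
  index per dish against the control group's mean quantities and
  reports mean ± SD — the mode that produces dispersion columns.
  `pooled` computes one value from group totals/pooled lengths (no SD)
  and is used for worked examples on group-level summary numbers. The
  modes coincide when dishes are identical.
- **VI magnitudes.** VI is implemented literally as G·(RL + SL) with G
  in percent, so a healthy wheat control scores VI ≈ 10³. Published
  tables in this assay family sometimes print VI on other scales;
  no rescaling is applied.
- **Degenerate dishes.** A dish with zero germinated seeds contributes
  G = 0 but has *undefined* RL/SL (an `UndefinedMeasureError` at the
  single-dish level); in group summaries it is skipped for length-based
  indices and the skip is logged. The exclusion rule (< 3 germinated,
  boundary inclusive) runs before any index computation.
- **Energy day.** The energy-day reading is per-crop configuration
  (day 3 for wheat/tomato; parsley is read only on the final day, so
  its records carry no energy count and Eg is undefined rather than 0).

## Membrane assays

Hemolysis, CF release and viability all normalise a signal between an
untreated reference (0%) and a total-effect reference (100%); the
percentages are therefore invariant under adding a constant to every
measurement, which the tests exercise. Negative percentages
(protective/quenching effects) are reported as-is with a below-baseline
interpretation left to the caller — clamping would hide data problems.

Endpoint conventions: leakage traces are truncated at the 20-minute
kinetic stop and the endpoint is the last sample at or before the
requested time (no interpolation). Replicates are aggregated as the
mean of replicate percentages, not the percentage of mean absorbances;
with shared references the two differ only when references vary per
replicate, and the former keeps replicate dispersion meaningful.

HC50/IC50 use a straight line of percent response on concentration
(linear scale), matching how such values are reported for weakly active
extracts, and are inverted at the 50% level. When the solution lies
outside the fitted concentration range — the typical case for a
non-hemolytic extract tested to 1000 µg/mL with HC50 in the thousands —
the summary carries an explicit extrapolation flag. A flat response
line yields NaN rather than an error, flagged likewise.

## Spearman correlations

Spearman's rho is the Pearson correlation of midranks (average ranks on
ties), delegated to `scipy.stats.spearmanr` behind the module surface
and cross-checked in the tests against a brute-force midrank oracle.
p-values use the t approximation t = ρ√((n−2)/(1−ρ²)) on n − 2 df; for
n ≤ 8 an exact permutation p (full enumeration of one variable's rank
permutations, two-sided on |ρ|) is available. |ρ| = 1 reports the
smallest positive float rather than zero. Missing data are handled by
pairwise deletion with a minimum of three complete pairs. Output tables
carry both ρ and ρ², since correlograms in this field are often
labelled with squared coefficients.

## Synthetic-data generators

Each generator draws from the statistical model its analysis assumes,
with the design sizes of a typical screen as defaults, and writes the
same CSV schemas the readers consume.

- **Mortality** (4 doses 250–2000 µg/mL × 10 larvae × 3 vessels,
  readings at 24/48 h by default): larva *i* carries u_i ~ N(0, 1) and
  is dead at time t iff log₁₀(dose) > logLC50(t) + u_i/slope, with
  logLC50(t) non-increasing in t (defaults 2.978 at 24 h, 2.624 at
  48 h; slope 4.45). This threshold construction makes cumulative
  counts monotone by design and gives the exact probit marginal
  Φ(slope·(log d − logLC50)) at every reading.
- **Germination** (5 dishes × 10 seeds; control germination p₀ = 0.72,
  control median root/shoot 6.9/7.9 cm): germination probability and
  median lengths are both scaled by 1 − E·cʰ/(cʰ + EC50ʰ)
  (E = 0.35, EC50 = 800 µg/mL, h = 1.5 — a moderate inhibition profile
  whose strongest effect sits at the top tested dose); lengths are
  lognormal (σ = 0.25); the energy-day count is a binomial thinning
  (fraction 0.65) of the final count, since the assay specifies no
  timing model.
- **Hemolysis / viability**: the true percentage follows a configured
  line (defaults: hemolysis 0.0067·c + 0.414, a weakly hemolytic
  profile reaching ~7% at 1000 µg/mL; viability −0.0367·c + 104.4, a
  biocompatible profile) with Gaussian noise, encoded back into
  absorbances between the configured references.
- **Leakage**: F(t) = F₀ + plateau·(F_T − F₀)(1 − e^(−kt)) truncated at
  1200 s; default plateau 0.0683 (≈6.8% release at the stop).

Identical config + seed yields identical records and, through the
writers, byte-identical files. What passing recovery tests on these
generators shows is that the *estimators* are correct and approximately
unbiased under the assumed models at the simulated sizes (the bias
check uses 500 datasets of 5 doses × 100 larvae; the single-dataset
recovery check 5 doses × 1000 larvae); they say nothing about model
misspecification on real data — overdispersion between vessels,
non-lognormal seedling lengths, or nonlinear hemolysis curves are
explicitly not emulated.

## Numerical and I/O choices

- Percent and probit arithmetic is double precision throughout;
  rounding happens only where a convention demands it (two-decimal
  probits) or at text rendering (2 decimals for percents, 4 for
  regression coefficients).
- CSV dialect is fixed: UTF-8, comma delimiter, dot decimal, required
  header; per-dish length vectors are semicolon-separated in one cell;
  floats are serialised with `repr` so read(write(x)) round-trips
  exactly. Readers validate row by row and report every offending line
  number at once.
- The pipeline report embeds no timestamps and serialises with sorted
  keys, so reruns on identical inputs are byte-identical; writes are
  atomic (temp file + rename).

## Known limitations

- The probit fit is unweighted OLS on (optionally rounded) probits;
  it has no fiducial or profile confidence limits. For
  publication-grade interval estimates a weighted ML probit (e.g.
  `statsmodels` GLM with a probit link on raw counts) is the right
  tool; this package intentionally reproduces the desk procedure.
- HC50/IC50 linearity is an assumption, adequate for weakly active
  extracts near the bottom of the response range and increasingly wrong
  approaching saturation; the extrapolation flag is the guard rail.
- The exact permutation p for Spearman enumerates n! permutations and
  is capped at n = 8.
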