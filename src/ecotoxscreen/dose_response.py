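"""Probit dose-response analysis for acute-lethality screens.

The brine-shrimp lethality test exposes batches of *Artemia salina* larvae
to a dilution series of an extract and counts cumulative deaths per dose
over time.  The classical desk analysis, which this module reproduces, is:

1. percent mortality per dose group (Abbott-corrected for background
   control mortality when that is non-zero);
2. replacement of 0% and 100% observed mortalities by 100·(0.25/n) and
   100·(n − 0.25)/n (Miller–Tainter), so extreme groups can enter the
   regression;
3. transformation to probability units, probit = 5 + Φ⁻¹(p), rounded to
   two decimals as when read from Finney's table;
4. ordinary least squares of probit on log10 concentration;
5. LC50 = 10^((5 − intercept)/slope), classified on Clarkson's scale.

A generic linear response-vs-concentration fit and its level inversion
(used for HC50 of a hemolysis curve or IC50 of a viability curve) live
here too, since they share the inversion arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import (
    EcotoxError,
    InvalidControlError,
    InvalidInputError,
    MustCorrectFirstError,
    NoLC50Error,
    ExtrapolationWarning,
    NonMonotoneResponseWarning,
)

__all__ = [
    "DoseGroup",
    "ProbitPoint",
    "ProbitFit",
    "LinearResponseLine",
    "mortality_rate",
    "abbott_correct",
    "miller_tainter_correct",
    "pct_to_probit",
    "fit_probit_line",
    "fit_probit_from_percentages",
    "lc50",
    "se_log_lc50",
    "classify_clarkson",
    "lc50_by_replicate",
    "validate_mortality_series",
    "fit_linear_response",
    "invert_linear_response",
]


@dataclass(frozen=True)
class DoseGroup:
    """One exposure vessel: cumulative deaths at a time point.

    Parameters
    ----------
    concentration : float
        Extract concentration, µg/mL; must be positive (log-dose model).
    n_total : int
        Organisms in the vessel at the start of the test.
    n_dead : int
        Cumulative deaths observed at ``time_h``.
    time_h : float
        Exposure time, hours.
    replicate_id : str, optional
        Vessel identifier when the design is replicated.
    """

    concentration: float
    n_total: int
    n_dead: int
    time_h: float
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise InvalidInputError(
                f"concentration must be positive, got {self.concentration}"
            )
        if self.n_total <= 0:
            raise InvalidInputError(f"n_total must be positive, got {self.n_total}")
        if not 0 <= self.n_dead <= self.n_total:
            raise InvalidInputError(
                f"n_dead={self.n_dead} outside [0, n_total={self.n_total}]"
            )


@dataclass(frozen=True)
class ProbitPoint:
    """One regression point: corrected mortality on the probit scale."""

    log10_dose: float
    raw_pct: float
    corrected_pct: float
    probit: float
    was_corrected: bool


@dataclass(frozen=True)
class ProbitFit:
    """OLS line of probit on log10 dose, with the derived LC50."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n_points: int
    log_lc50: float
    lc50: float
    points: tuple[ProbitPoint, ...] = field(default=())

    def predict(self, log10_dose: float) -> float:
        return self.slope * log10_dose + self.intercept


@dataclass(frozen=True)
class LinearResponseLine:
    """OLS line of a percentage response on concentration (linear scale)."""

    slope: float
    intercept: float
    response_label: str = "response"
    r_squared: float | None = None
    conc_range: tuple[float, float] | None = None

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def mortality_rate(n_dead: int, n_total: int) -> float:
    """Percent mortality, 100·n_dead/n_total."""
    if n_total <= 0:
        raise InvalidInputError("n_total must be positive")
    if not 0 <= n_dead <= n_total:
        raise InvalidInputError(f"n_dead={n_dead} outside [0, {n_total}]")
    return 100.0 * n_dead / n_total

def abbott_correct(treated_pct: float, control_pct: float) -> float:
    """Correct treated mortality for background control mortality.

    Abbott's formula, 100·(T − C)/(100 − C).  With zero control mortality
    the correction is the identity.  Output is clamped below at 0 (a
    treated group can fall below the control by sampling noise).
    """
    if not 0 <= control_pct < 100:
        raise InvalidControlError(
            f"control mortality must be in [0, 100), got {control_pct}"
        )
    corrected = 100.0 * (treated_pct - control_pct) / (100.0 - control_pct)
    return max(corrected, 0.0)


def miller_tainter_correct(pct: float, n: int) -> float:
    """Replace extreme 0%/100% mortalities so they can be probit-transformed.

    0%  -> 100·(0.25/n);  100% -> 100·(n − 0.25)/n;  interior values pass
    through unchanged.  With n = 10 the replacements are 2.5% and 97.5%,
    whose probits round to 3.04 and 6.96.
    """
    if n < 1:
        raise InvalidInputError("group size n must be >= 1")
    if not 0 <= pct <= 100:
        raise InvalidInputError(f"percent mortality outside [0, 100]: {pct}")
    if pct == 0.0:
        return 100.0 * 0.25 / n
    if pct == 100.0:
        return 100.0 * (n - 0.25) / n
    return pct


def pct_to_probit(pct: float, round_dp: int | None = 2) -> float:
    """Probability unit: 5 + standard-normal quantile of pct/100.

    ``round_dp`` reproduces reading the value off a printed probit table
    (two decimals by default); pass ``None`` for the full-precision value.
    """
    if not 0 < pct < 100:
        raise MustCorrectFirstError(
            f"probit undefined at {pct}%: apply miller_tainter_correct first"
        )
    value = 5.0 + stats.norm.ppf(pct / 100.0)
    if round_dp is not None:
        value = round(value, round_dp)
    return value


def fit_probit_line(
    groups: Sequence[DoseGroup],
    *,
    probit_round: int | None = 2,
    control_pct: float = 0.0,
) -> ProbitFit:
    """Fit the probit line to dose groups sharing one time point.

    Each group contributes one point: mortality percent, Abbott-corrected
    if ``control_pct`` > 0, Miller–Tainter-corrected if extreme, then
    probit-transformed (rounded to ``probit_round`` decimals).  The OLS
    regressor is the full-precision log10 concentration.  The two-sided
    p-value is the t test on the correlation with n − 2 df.

    Raises on fewer than two distinct concentrations; a non-positive
    slope triggers a :class:`NonMonotoneResponseWarning`.
    """
    if not groups:
        raise InvalidInputError("no dose groups supplied")
    times = {g.time_h for g in groups}
    if len(times) != 1:
        raise InvalidInputError(f"groups span several time points: {sorted(times)}")
    concs = sorted({g.concentration for g in groups})
    if len(concs) < 2:
        raise InvalidInputError("need at least 2 distinct concentrations")

    # pool replicate vessels at the same concentration
    points: list[ProbitPoint] = []
    for conc in concs:
        members = [g for g in groups if g.concentration == conc]
        n_dead = sum(g.n_dead for g in members)
        n_total = sum(g.n_total for g in members)
        raw = mortality_rate(n_dead, n_total)
        pct = abbott_correct(raw, control_pct) if control_pct > 0 else raw
        corrected = miller_tainter_correct(pct, n_total)
        points.append(
            ProbitPoint(
                log10_dose=math.log10(conc),
                raw_pct=raw,
                corrected_pct=corrected,
                probit=pct_to_probit(corrected, probit_round),
                was_corrected=(corrected != pct),
            )
        )

    return _fit_points(points)


def fit_probit_from_percentages(
    concentrations: Sequence[float],
    mortality_pcts: Sequence[float],
    n_per_group: int,
    *,
    probit_round: int | None = 2,
    control_pct: float = 0.0,
) -> ProbitFit:
    """Fit the probit line from per-dose mean mortality percentages.

    The classical desk workflow records one mortality percent per dose
    (often the mean over replicate vessels) alongside the per-vessel
    group size, which is what the Miller–Tainter replacement needs.
    Corrections and regression are identical to :func:`fit_probit_line`.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(mortality_pcts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("concentrations and percentages must match in length")
    if len(np.unique(x)) < 2:
        raise InvalidInputError("need at least 2 distinct concentrations")
    if np.any(x <= 0):
        raise InvalidInputError("concentrations must be positive")
    points = []
    for conc, raw in zip(x, y):
        pct = abbott_correct(raw, control_pct) if control_pct > 0 else float(raw)
        corrected = miller_tainter_correct(pct, n_per_group)
        points.append(
            ProbitPoint(
                log10_dose=math.log10(conc),
                raw_pct=float(raw),
                corrected_pct=corrected,
                probit=pct_to_probit(corrected, probit_round),
                was_corrected=(corrected != pct),
            )
        )
    return _fit_points(points)


def _fit_points(points: list[ProbitPoint]) -> ProbitFit:
    x = np.array([p.log10_dose for p in points])
    y = np.array([p.probit for p in points])
    res = stats.linregress(x, y)
    if res.slope <= 0:
        warnings.warn(
            f"non-positive probit slope {res.slope:.4g}: mortality does not "
            "increase with dose",
            NonMonotoneResponseWarning,
            stacklevel=3,
        )
        log_lc50 = math.nan
        lc50_value = math.nan
    else:
        log_lc50 = (5.0 - res.intercept) / res.slope
        lc50_value = 10.0 ** log_lc50
    return ProbitFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(points),
        log_lc50=log_lc50,
        lc50=lc50_value,
        points=tuple(points),
    )


def lc50(fit: ProbitFit) -> float:
    """Median lethal concentration from a fitted probit line, µg/mL."""
    if not fit.slope > 0:
        raise NoLC50Error(f"slope must be positive, got {fit.slope}")
    return 10.0 ** ((5.0 - fit.intercept) / fit.slope)


def se_log_lc50(fit: ProbitFit, n_per_group: int) -> float:
    """Approximate standard error of log10 LC50 (Miller–Tainter style).

    (log LC84 − log LC16) / sqrt(2·n_per_group), where LC84 and LC16
    solve the fitted line at probits 6 and 4.
    """
    if not fit.slope > 0:
        raise NoLC50Error("slope must be positive")
    if n_per_group < 1:
        raise InvalidInputError("n_per_group must be >= 1")
    log_lc84 = (6.0 - fit.intercept) / fit.slope
    log_lc16 = (4.0 - fit.intercept) / fit.slope
    return (log_lc84 - log_lc16) / math.sqrt(2 * n_per_group)


ClarksonCategory = Literal["non-toxic", "low", "medium", "high"]

#: Clarkson's criterion for plant extracts, upper-inclusive bounds in µg/mL.
CLARKSON_BOUNDS: tuple[tuple[float, ClarksonCategory], ...] = (
    (100.0, "high"),
    (500.0, "medium"),
    (1000.0, "low"),
    (math.inf, "non-toxic"),
)


def classify_clarkson(lc50_value: float) -> ClarksonCategory:
    """Clarkson toxicity class of an LC50 in µg/mL.

    (0, 100] high; (100, 500] medium; (500, 1000] low; above 1000 (i.e.
    above 1 mg/mL) non-toxic.
    """
    if not lc50_value > 0:
        raise InvalidInputError(f"LC50 must be positive, got {lc50_value}")
    for upper, category in CLARKSON_BOUNDS:
        if lc50_value <= upper:
            return category
    raise AssertionError("unreachable")


def lc50_by_replicate(
    groups: Sequence[DoseGroup],
    *,
    probit_round: int | None = 2,
    control_pct: float = 0.0,
) -> tuple[float, float, list[float]]:
    """Per-replicate LC50 estimates summarised as mean ± SD.

    Splits the dose groups by ``replicate_id``, fits one probit line per
    replicate, and returns (mean LC50, SD, individual estimates).  The
    pooled fit remains the headline estimate; this dispersion is how a
    "± value" on an LC50 is read when replicate vessels exist.
    """
    ids = sorted({g.replicate_id for g in groups}, key=str)
    if len(ids) < 2 or None in ids:
        raise InvalidInputError("per-replicate LC50 needs >= 2 labelled replicates")
    estimates = []
    for rid in ids:
        fit = fit_probit_line(
            [g for g in groups if g.replicate_id == rid],
            probit_round=probit_round,
            control_pct=control_pct,
        )
        estimates.append(fit.lc50)
    arr = np.asarray(estimates, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), estimates


def validate_mortality_series(groups: Sequence[DoseGroup]) -> None:
    """Check cumulative death counts never decrease in time.

    Applies within each (concentration, replicate_id) series; a violation
    raises rather than being silently repaired, since it indicates a
    recording error.
    """
    keys = sorted({(g.concentration, g.replicate_id) for g in groups}, key=str)
    bad: list[str] = []
    for conc, rid in keys:
        series = sorted(
            (g for g in groups if g.concentration == conc and g.replicate_id == rid),
            key=lambda g: g.time_h,
        )
        for earlier, later in zip(series, series[1:]):
            if later.n_dead < earlier.n_dead:
                bad.append(
                    f"concentration {conc}, replicate {rid}: n_dead drops "
                    f"{earlier.n_dead} -> {later.n_dead} "
                    f"between {earlier.time_h} h and {later.time_h} h"
                )
    if bad:
        raise EcotoxError(
            "cumulative mortality must be non-decreasing in time:\n" + "\n".join(bad)
        )


def fit_linear_response(
    concentrations: Sequence[float],
    responses: Sequence[float],
    *,
    response_label: str = "response",
) -> LinearResponseLine:
    """OLS line of a response (e.g. % hemolysis, % viability) on concentration."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("concentrations and responses must be equal-length 1-D")
    if len(np.unique(x)) < 2:
        raise InvalidInputError("need at least 2 distinct concentrations")
    res = stats.linregress(x, y)
    return LinearResponseLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        response_label=response_label,
        r_squared=float(res.rvalue**2),
        conc_range=(float(x.min()), float(x.max())),
    )


def invert_linear_response(line: LinearResponseLine, level: float = 50.0) -> float:
    """Concentration at which the fitted line reaches ``level``.

    Solves level = slope·c + intercept.  Emits an
    :class:`ExtrapolationWarning` when the solution lies outside the
    fitted concentration range (when known) and when it is non-positive;
    the value is still returned so callers can report it with a flag.
    """
    if line.slope == 0:
        raise InvalidInputError("cannot invert a zero-slope response line")
    conc = (level - line.intercept) / line.slope
    if conc <= 0:
        warnings.warn(
            f"inverted {line.response_label} level {level} at non-positive "
            f"concentration {conc:.4g} µg/mL",
            ExtrapolationWarning,
            stacklevel=2,
        )
    elif line.conc_range is not None and not (
        line.conc_range[0] <= conc <= line.conc_range[1]
    ):
        warnings.warn(
            f"{line.response_label} level {level} reached at {conc:.4g} µg/mL, "
            f"outside the fitted range {line.conc_range}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return conc
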