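"""Membrane-interaction assays: hemolysis, dye leakage, cell viability.

All three assays reduce to the same normalisation: a measured signal
placed between an untreated reference (0%) and a total-effect reference
(100%).  For hemolysis the signal is supernatant absorbance at 576 nm
between intact cells and water-lysed cells; for carboxyfluorescein (CF)
leakage it is fluorescence at 520 nm between intact vesicles and
detergent-burst vesicles; for MTS viability it is absorbance at 490 nm
relative to untreated control wells.

``assay_summary`` aggregates replicate percentages per concentration,
fits the straight response-vs-concentration line and inverts it at a
level (50% by default), yielding HC50 or IC50 with extrapolation flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dose_response import (
    LinearResponseLine,
    fit_linear_response,
    invert_linear_response,
)
from .errors import InvalidControlError, InvalidInputError, ExtrapolationWarning

__all__ = [
    "HemolysisSample",
    "LeakageTrace",
    "ViabilityRecord",
    "AssaySummary",
    "hemolysis_pct",
    "cf_release_pct",
    "viability_pct",
    "hemolysis_category",
    "assay_summary",
]

#: kinetic stop for leakage traces, seconds (20 min)
LEAKAGE_STOP_S = 1200.0


@dataclass(frozen=True)
class HemolysisSample:
    """Absorbance triplet of one hemolysis measurement (576 nm)."""

    concentration: float
    replicate_id: str
    a_sample: float
    a_control: float
    a_100: float

    def __post_init__(self) -> None:
        if min(self.a_sample, self.a_control, self.a_100) < 0:
            raise InvalidInputError("absorbances must be non-negative")
        if not self.a_100 > self.a_control:
            raise InvalidControlError(
                f"total-lysis absorbance {self.a_100} must exceed the "
                f"untreated control {self.a_control}"
            )


@dataclass(frozen=True)
class LeakageTrace:
    """Fluorescence time course of CF escape from vesicles (520 nm).

    ``f0`` is the baseline before extract addition; ``f_total`` the
    intensity after detergent burst.  Times must increase strictly and
    the trace is truncated at the 20-minute kinetic stop on creation.
    """

    fraction_label: str
    times_s: tuple[float, ...]
    fluorescence: tuple[float, ...]
    f0: float
    f_total: float

    def __post_init__(self) -> None:
        if not self.f_total > self.f0:
            raise InvalidControlError(
                f"f_total={self.f_total} must exceed baseline f0={self.f0}"
            )
        if len(self.times_s) != len(self.fluorescence) or not self.times_s:
            raise InvalidInputError("times and fluorescence must be equal, non-empty")
        if any(b <= a for a, b in zip(self.times_s, self.times_s[1:])):
            raise InvalidInputError("times must be strictly increasing")
        if self.times_s[-1] > LEAKAGE_STOP_S:
            keep = [i for i, t in enumerate(self.times_s) if t <= LEAKAGE_STOP_S]
            object.__setattr__(self, "times_s", tuple(self.times_s[i] for i in keep))
            object.__setattr__(
                self, "fluorescence", tuple(self.fluorescence[i] for i in keep)
            )


@dataclass(frozen=True)
class ViabilityRecord:
    """One MTS well: absorbance at 490 nm, flagged if an untreated control."""

    cell_line: str
    concentration: float
    replicate_id: str
    absorbance: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise InvalidInputError("absorbance must be non-negative")


def hemolysis_pct(s: HemolysisSample) -> float:
    """Percent hemolysis, 100·(A_sample − A_control)/(A_100 − A_control).

    Negative values (extract below untreated baseline, e.g. a protective
    or quenching effect) are returned as-is, not clamped.
    """
    return 100.0 * (s.a_sample - s.a_control) / (s.a_100 - s.a_control)


def cf_release_pct(trace: LeakageTrace, t: float = LEAKAGE_STOP_S) -> float:
    """Percent CF released at the latest sampled time <= ``t``.

    100·(F_t − F_0)/(F_T − F_0); no interpolation or extrapolation is
    performed — the endpoint convention is the last recorded sample.
    """
    if t < trace.times_s[0]:
        raise InvalidInputError(
            f"t={t}s precedes the first sample at {trace.times_s[0]}s"
        )
    idx = max(i for i, ts in enumerate(trace.times_s) if ts <= t)
    f_t = trace.fluorescence[idx]
    return 100.0 * (f_t - trace.f0) / (trace.f_total - trace.f0)


def viability_pct(treated_mean_abs: float, control_mean_abs: float) -> float:
    """Percent viability: treated absorbance relative to untreated control."""
    if not control_mean_abs > 0:
        raise InvalidControlError("control absorbance must be positive")
    if treated_mean_abs < 0:
        raise InvalidInputError("absorbance must be non-negative")
    return 100.0 * treated_mean_abs / control_mean_abs


def hemolysis_category(pct: float) -> Literal["none", "low", "marked"]:
    """Regulatory-style label: <5% none, 5-10% low, >10% marked."""
    if pct < 5.0:
        return "none"
    if pct <= 10.0:
        return "low"
    return "marked"


@dataclass(frozen=True)
class AssaySummary:
    """Per-concentration table plus fitted line and inverted level."""

    table: pd.DataFrame
    line: LinearResponseLine
    level: float
    inverted_concentration: float
    extrapolated: bool
    below_zero: bool

    def __repr__(self) -> str:  # keep the frame out of the one-line repr
        return (
            f"AssaySummary(level={self.level}, "
            f"inverted_concentration={self.inverted_concentration:.4g}, "
            f"extrapolated={self.extrapolated}, line={self.line!r})"
        )


def assay_summary(
    concentrations: Sequence[float],
    percentages: Sequence[float],
    *,
    level: float = 50.0,
    response_label: str = "response",
) -> AssaySummary:
    """Summarise replicate percentages and locate the 50% concentration.

    ``concentrations``/``percentages`` are per-replicate pairs; replicate
    percentages are averaged per concentration (mean of percentages, not
    percentage of mean signals), the line is fitted on the replicate-level
    points, and the requested level is inverted with extrapolation flags.
    """
    conc = np.asarray(concentrations, dtype=float)
    pct = np.asarray(percentages, dtype=float)
    if conc.shape != pct.shape:
        raise InvalidInputError("concentrations and percentages differ in length")
    df = pd.DataFrame({"concentration": conc, "pct": pct})
    table = (
        df.groupby("concentration", sort=True)["pct"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        .reset_index()
    )
    line = fit_linear_response(conc, pct, response_label=response_label)
    if line.slope == 0:
        # flat response (e.g. viability pinned at 100%): no finite level
        inverted = math.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            inverted = invert_linear_response(line, level=level)
    below_zero = inverted <= 0 or not math.isfinite(inverted)
    lo, hi = line.conc_range
    extrapolated = below_zero or not (lo <= inverted <= hi)
    return AssaySummary(
        table=table,
        line=line,
        level=level,
        inverted_concentration=inverted,
        extrapolated=extrapolated,
        below_zero=below_zero,
    )
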