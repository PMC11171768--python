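"""Seeded generators emulating each screening assay's statistical structure.

The generators produce the same record types and CSV schemas the readers
consume, so every analysis stage can be exercised end to end — and
parameter recovery can be checked against known ground truth — without
external data.  Each configuration carries its own seed; identical
config + seed yields identical output.

What is emulated (and what is not): the *statistical* structure the
analysis assumes — binomial mortality under a log10-dose probit
tolerance model, binomial germination with Hill-type inhibition and
lognormal seedling lengths, linear-in-concentration hemolysis/viability
with Gaussian noise, first-order dye release.  No mechanistic biology
(allelochemical kinetics, membrane physics) is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose_response import DoseGroup
from .errors import InvalidControlError, InvalidInputError
from .germination import GerminationReplicate
from .membrane import HemolysisSample, LeakageTrace, ViabilityRecord

__all__ = [
    "MortalitySimConfig",
    "GerminationSimConfig",
    "HemolysisSimConfig",
    "ViabilitySimConfig",
    "LeakageSimConfig",
    "simulate_mortality",
    "simulate_germination",
    "simulate_hemolysis",
    "simulate_viability",
    "simulate_leakage",
]


# ---------------------------------------------------------------- mortality
@dataclass(frozen=True)
class MortalitySimConfig:
    """Brine-shrimp lethality design: dilution series x vessels x times.

    The tolerance model: larva i carries u_i ~ N(0, 1); it is dead at
    time t iff log10(dose) > log_lc50(t) + u_i/slope, where log_lc50(t)
    (linearly interpolated between the configured time points) is
    non-increasing in t.  Cumulative counts are therefore monotone by
    construction, and terminal mortality has probability
    Phi(slope·(log10 dose − log_lc50(T))).

    Defaults mirror a typical acute screen: 4 concentrations, 10 larvae
    per vessel, 3 vessels, readings at 24 h and 48 h, median tolerance
    falling from ~951 µg/mL at 24 h to ~421 µg/mL at 48 h with probit
    slope 4.45.
    """

    seed: int = 0
    doses: tuple[float, ...] = (250.0, 500.0, 1000.0, 2000.0)
    n_per_group: int = 10
    n_replicates: int = 3
    time_points_h: tuple[float, ...] = (24.0, 48.0)
    log_lc50_by_time: tuple[tuple[float, float], ...] = ((24.0, 2.978), (48.0, 2.624))
    slope: float = 4.45

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidInputError("probit slope must be positive")
        if min(self.doses) <= 0 or len(set(self.doses)) != len(self.doses):
            raise InvalidInputError("doses must be distinct and positive")
        if self.n_per_group < 1 or self.n_replicates < 1:
            raise InvalidInputError("counts must be positive")
        lls = [v for _, v in sorted(self.log_lc50_by_time)]
        if any(b > a for a, b in zip(lls, lls[1:])):
            raise InvalidInputError("log_lc50 must be non-increasing in time")

    def log_lc50_at(self, t: float) -> float:
        ts, vs = zip(*sorted(self.log_lc50_by_time))
        return float(np.interp(t, ts, vs))


def simulate_mortality(config: MortalitySimConfig) -> list[DoseGroup]:
    """Draw cumulative death counts for every dose x vessel x time."""
    rng = np.random.default_rng(config.seed)
    groups: list[DoseGroup] = []
    for dose in config.doses:
        logd = math.log10(dose)
        for rep in range(config.n_replicates):
            u = rng.standard_normal(config.n_per_group)
            for t in sorted(config.time_points_h):
                threshold = config.log_lc50_at(t) + u / config.slope
                n_dead = int(np.sum(logd > threshold))
                groups.append(
                    DoseGroup(
                        concentration=dose,
                        n_total=config.n_per_group,
                        n_dead=n_dead,
                        time_h=t,
                        replicate_id=f"R{rep + 1}",
                    )
                )
    return groups


# -------------------------------------------------------------- germination
@dataclass(frozen=True)
class GerminationSimConfig:
    """Petri-dish germination design with Hill-type inhibition.

    Germination probability at concentration c is
    p0·(1 − emax·c^h/(c^h + ec50^h)); seedling root and shoot lengths
    are lognormal with median scaled by the same inhibition factor.
    The energy-day count is a binomial thinning (fraction
    ``energy_fraction``) of the final count.  Defaults mirror a wheat
    screen: 5 dishes x 10 seeds, control germination 72%, control median
    root/shoot 6.9/7.9 cm.
    """

    seed: int = 0
    concentrations: tuple[float, ...] = (125.0, 250.0, 500.0, 1000.0)
    n_replicates: int = 5
    n_seeds: int = 10
    p0: float = 0.72
    emax: float = 0.35
    ec50: float = 800.0
    hill: float = 1.5
    energy_fraction: float = 0.65
    root_median_cm: float = 6.9
    shoot_median_cm: float = 7.9
    length_sigma: float = 0.25
    crop: str = "wheat"

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise InvalidInputError("p0 must be in (0, 1]")
        if not 0 <= self.emax <= 1:
            raise InvalidInputError("emax must be in [0, 1]")
        if not 0 <= self.energy_fraction <= 1:
            raise InvalidInputError("energy_fraction must be in [0, 1]")
        if self.ec50 <= 0 or self.hill <= 0 or self.length_sigma < 0:
            raise InvalidInputError("ec50, hill must be positive; sigma non-negative")

    def inhibition(self, concentration: float) -> float:
        """Fractional inhibition in [0, emax] at a concentration."""
        if concentration <= 0:
            return 0.0
        ch = concentration**self.hill
        return self.emax * ch / (ch + self.ec50**self.hill)


def simulate_germination(config: GerminationSimConfig) -> list[GerminationReplicate]:
    """Draw dishes for the control and every configured concentration."""
    rng = np.random.default_rng(config.seed)
    out: list[GerminationReplicate] = []
    for conc in (None, *config.concentrations):
        inhibition = config.inhibition(0.0 if conc is None else conc)
        p = config.p0 * (1.0 - inhibition)
        scale = 1.0 - inhibition
        label = "control" if conc is None else f"{conc:g} ug/mL"
        for rep in range(config.n_replicates):
            n_final = int(rng.binomial(config.n_seeds, p))
            n_energy = int(rng.binomial(n_final, config.energy_fraction))
            roots = tuple(
                float(v)
                for v in rng.lognormal(
                    math.log(config.root_median_cm * scale),
                    config.length_sigma,
                    n_final,
                )
            )
            shoots = tuple(
                float(v)
                for v in rng.lognormal(
                    math.log(config.shoot_median_cm * scale),
                    config.length_sigma,
                    n_final,
                )
            )
            out.append(
                GerminationReplicate(
                    condition=label,
                    concentration=conc,
                    replicate_id=f"R{rep + 1}",
                    n_seeds=config.n_seeds,
                    n_germ_energy=n_energy,
                    n_germ_final=n_final,
                    root_lengths=roots,
                    shoot_lengths=shoots,
                )
            )
    return out


# ---------------------------------------------------- hemolysis / viability
@dataclass(frozen=True)
class HemolysisSimConfig:
    """Linear hemolysis response with Gaussian noise on the percentage.

    True percent hemolysis at concentration c is slope·c + intercept;
    the generated absorbance triplet encodes that percentage between the
    configured references.  Defaults follow a mild hemolysis line
    (~7% at 1000 µg/mL) over a 125-1000 µg/mL series in triplicate.
    """

    seed: int = 0
    concentrations: tuple[float, ...] = (125.0, 250.0, 500.0, 1000.0)
    n_replicates: int = 3
    slope: float = 0.0067
    intercept: float = 0.414
    noise_sd_pct: float = 0.5
    a_control: float = 0.10
    a_100: float = 1.10

    def __post_init__(self) -> None:
        if not self.a_100 > self.a_control:
            raise InvalidControlError("a_100 must exceed a_control")
        if self.noise_sd_pct < 0:
            raise InvalidInputError("noise sd must be non-negative")


def simulate_hemolysis(config: HemolysisSimConfig) -> list[HemolysisSample]:
    rng = np.random.default_rng(config.seed)
    span = config.a_100 - config.a_control
    out = []
    for conc in config.concentrations:
        for rep in range(config.n_replicates):
            pct = config.slope * conc + config.intercept
            pct += rng.normal(0.0, config.noise_sd_pct) if config.noise_sd_pct else 0.0
            out.append(
                HemolysisSample(
                    concentration=conc,
                    replicate_id=f"R{rep + 1}",
                    a_sample=config.a_control + pct / 100.0 * span,
                    a_control=config.a_control,
                    a_100=config.a_100,
                )
            )
    return out


@dataclass(frozen=True)
class ViabilitySimConfig:
    """MTS viability declining linearly with concentration.

    True viability % is slope·c + intercept (slope typically negative);
    well absorbance is control_abs·pct/100 plus Gaussian noise.  The
    defaults give ~104% at 10 µg/mL falling to ~86% at 500 µg/mL, a
    biocompatible profile whose IC50 lies far above the tested range.
    """

    seed: int = 0
    cell_line: str = "HGF"
    concentrations: tuple[float, ...] = (10.0, 50.0, 100.0, 250.0, 500.0)
    n_replicates: int = 3
    slope: float = -0.0367
    intercept: float = 104.4
    noise_sd_abs: float = 0.01
    control_abs: float = 0.50
    n_control: int = 3

    def __post_init__(self) -> None:
        if self.control_abs <= 0:
            raise InvalidControlError("control absorbance must be positive")


def simulate_viability(config: ViabilitySimConfig) -> list[ViabilityRecord]:
    rng = np.random.default_rng(config.seed)
    out = [
        ViabilityRecord(
            cell_line=config.cell_line,
            concentration=0.0,
            replicate_id=f"C{i + 1}",
            absorbance=max(
                0.0, config.control_abs + float(rng.normal(0, config.noise_sd_abs))
            ),
            is_control=True,
        )
        for i in range(config.n_control)
    ]
    for conc in config.concentrations:
        for rep in range(config.n_replicates):
            pct = config.slope * conc + config.intercept
            absorbance = config.control_abs * pct / 100.0
            absorbance += float(rng.normal(0, config.noise_sd_abs))
            out.append(
                ViabilityRecord(
                    cell_line=config.cell_line,
                    concentration=conc,
                    replicate_id=f"R{rep + 1}",
                    absorbance=max(0.0, absorbance),
                )
            )
    return out


# ------------------------------------------------------------------ leakage
@dataclass(frozen=True)
class LeakageSimConfig:
    """First-order CF release: F(t) = F0 + plateau·(FT − F0)·(1 − e^(−kt)).

    ``plateau`` is the released fraction at infinite time; the default
    0.0683 reproduces a weakly membrane-active extract (≈6.8% release at
    the 20-min stop).  Gaussian noise is added to the fluorescence.
    """

    seed: int = 0
    fraction_label: str = "200 ug"
    k_per_s: float = 0.01
    plateau: float = 0.0683
    f0: float = 10.0
    f_total: float = 110.0
    dt_s: float = 10.0
    t_max_s: float = 1200.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.k_per_s <= 0:
            raise InvalidInputError("rate k must be positive")
        if not 0 < self.plateau <= 1:
            raise InvalidInputError("plateau fraction must be in (0, 1]")
        if not self.f_total > self.f0:
            raise InvalidControlError("f_total must exceed f0")


def simulate_leakage(config: LeakageSimConfig) -> LeakageTrace:
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.t_max_s + config.dt_s / 2, config.dt_s)
    span = config.f_total - config.f0
    f = config.f0 + config.plateau * span * (1.0 - np.exp(-config.k_per_s * times))
    if config.noise_sd:
        f = f + rng.normal(0.0, config.noise_sd, size=f.shape)
    return LeakageTrace(
        fraction_label=config.fraction_label,
        times_s=tuple(float(t) for t in times),
        fluorescence=tuple(float(v) for v in f),
        f0=config.f0,
        f_total=config.f_total,
    )
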