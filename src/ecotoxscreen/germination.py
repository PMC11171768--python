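"""Seed-germination phytotoxicity indices.

A germination screen places a fixed number of seeds per Petri dish in an
extract dilution (or water for the control), reads germination counts on
an early "energy" day and a final day, and measures root and shoot
lengths of the germinated seedlings.  Nine indices summarise the outcome
per group, the relative ones always against the water control:

=====  ===============================================================
Eg     germinative energy, % germinated by the energy day
G      germination rate, % germinated at the final reading
RL     mean root length, cm
SL     mean shoot length, cm
RRG    relative root growth, 100·RL/RL_control
RSG    relative seed germination, 100·germinated/germinated_control
GI     germination index, G·RRG/100
VI     vigor index, G·(RL + SL)
PI     aerial influence index, 100·(G·SL)/(G·SL)_control
=====  ===============================================================

Dishes with fewer than three germinated seeds are excluded before any
index is computed (``exclude_sparse_groups``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyGroupError,
    InvalidControlError,
    InvalidInputError,
    UndefinedMeasureError,
)

__all__ = [
    "GerminationReplicate",
    "IndexSummary",
    "GerminationIndices",
    "germination_energy",
    "germination_rate",
    "mean_length",
    "relative_root_growth",
    "relative_seed_germination",
    "germination_index",
    "vigor_index",
    "aerial_influence_index",
    "exclude_sparse_groups",
    "compute_group_indices",
]

logger = logging.getLogger(__name__)

INDEX_NAMES = ("Eg", "G", "RL", "SL", "RRG", "RSG", "GI", "VI", "PI")


@dataclass(frozen=True)
class GerminationReplicate:
    """One Petri dish of a germination test.

    ``concentration`` is None for the water control.  ``root_lengths``
    and ``shoot_lengths`` carry one value per germinated seedling, each
    already the mean over that seedling's root strands (strand-level
    averaging happens at measurement time).  ``n_germ_energy`` is None
    for crops without an energy-day reading (e.g. parsley, read only on
    the final day).
    """

    condition: str
    concentration: float | None
    replicate_id: str
    n_seeds: int
    n_germ_energy: int | None
    n_germ_final: int
    root_lengths: tuple[float, ...] = ()
    shoot_lengths: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_seeds <= 0:
            raise InvalidInputError("n_seeds must be positive")
        if self.concentration is not None and self.concentration < 0:
            raise InvalidInputError("concentration must be non-negative")
        if not 0 <= self.n_germ_final <= self.n_seeds:
            raise InvalidInputError(
                f"n_germ_final={self.n_germ_final} outside [0, {self.n_seeds}]"
            )
        if self.n_germ_energy is not None and not (
            0 <= self.n_germ_energy <= self.n_germ_final
        ):
            raise InvalidInputError(
                f"n_germ_energy={self.n_germ_energy} outside "
                f"[0, n_germ_final={self.n_germ_final}]"
            )
        for name in ("root_lengths", "shoot_lengths"):
            vals = getattr(self, name)
            if len(vals) > self.n_germ_final:
                raise InvalidInputError(
                    f"{name} has {len(vals)} entries but only "
                    f"{self.n_germ_final} seedlings germinated"
                )
            if any(v < 0 for v in vals):
                raise InvalidInputError(f"{name} contains negative values")


def germination_energy(rep: GerminationReplicate) -> float:
    """Percent of seeds germinated by the energy-day reading."""
    if rep.n_germ_energy is None:
        raise UndefinedMeasureError(
            f"replicate {rep.replicate_id}: no energy-day reading recorded"
        )
    return 100.0 * rep.n_germ_energy / rep.n_seeds


def germination_rate(rep: GerminationReplicate) -> float:
    """Percent of seeds germinated at the final reading."""
    return 100.0 * rep.n_germ_final / rep.n_seeds


def mean_length(values: Sequence[float]) -> float:
    """Mean seedling length; raises UndefinedMeasureError on no seedlings."""
    if len(values) == 0:
        raise UndefinedMeasureError("mean length undefined for zero seedlings")
    return fmean(values)


def relative_root_growth(sample_mean_rl: float, control_mean_rl: float) -> float:
    """RRG: sample mean root length as a percent of the control's."""
    if not control_mean_rl > 0:
        raise InvalidControlError("control mean root length must be positive")
    return 100.0 * sample_mean_rl / control_mean_rl


def relative_seed_germination(
    sample_germinated: float, control_germinated: float
) -> float:
    """RSG: germinated seeds as a percent of the control's count."""
    if not control_germinated > 0:
        raise InvalidControlError("control germinated count must be positive")
    return 100.0 * sample_germinated / control_germinated


def germination_index(g: float, rrg: float) -> float:
    """GI = G · RRG / 100, a combined germination-and-root-growth index.

    Scaled so that a group identical to its control (RRG = 100) has
    GI = G; this is the convention under which control columns of a
    report read GI = G.
    """
    if g < 0 or rrg < 0:
        raise InvalidInputError("G and RRG must be non-negative")
    return g * rrg / 100.0


def vigor_index(g: float, mean_rl: float, mean_sl: float) -> float:
    """VI = G · (mean root length + mean shoot length)."""
    if g < 0 or mean_rl < 0 or mean_sl < 0:
        raise InvalidInputError("vigor index inputs must be non-negative")
    return g * (mean_rl + mean_sl)


def aerial_influence_index(
    g_sample: float, sl_sample: float, g_control: float, sl_control: float
) -> float:
    """PI = 100 · (G·SL)_sample / (G·SL)_control, the aerial-part index."""
    denom = g_control * sl_control
    if not denom > 0:
        raise InvalidControlError("control G x SL product must be positive")
    return 100.0 * (g_sample * sl_sample) / denom


def exclude_sparse_groups(
    replicates: Iterable[GerminationReplicate], min_germinated: int = 3
) -> tuple[list[GerminationReplicate], list[tuple[GerminationReplicate, str]]]:
    """Drop dishes with fewer than ``min_germinated`` germinated seeds.

    Returns (retained, excluded) with a reason string per exclusion;
    order is preserved and every exclusion is logged.  The boundary is
    inclusive: a dish with exactly ``min_germinated`` is retained.
    """
    if min_germinated < 1:
        raise InvalidInputError("min_germinated must be >= 1")
    retained, excluded = [], []
    for rep in replicates:
        if rep.n_germ_final < min_germinated:
            reason = (
                f"{rep.condition}/{rep.replicate_id}: {rep.n_germ_final} "
                f"germinated < minimum {min_germinated}"
            )
            logger.info("excluding replicate: %s", reason)
            excluded.append((rep, reason))
        else:
            retained.append(rep)
    if not retained:
        raise EmptyGroupError(
            f"all {len(excluded)} replicates excluded (min {min_germinated} germinated)"
        )
    return retained, excluded


@dataclass(frozen=True)
class IndexSummary:
    mean: float
    sd: float | None
    n: int


@dataclass(frozen=True)
class GerminationIndices:
    """The nine indices of one condition group, mean (± SD across dishes)."""

    condition: str
    mode: Literal["per_replicate", "pooled"]
    values: dict[str, IndexSummary]

    def __getitem__(self, key: str) -> IndexSummary:
        return self.values[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"index": k, "mean": v.mean, "sd": v.sd, "n": v.n}
            for k, v in self.values.items()
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "condition", self.condition)
        df.insert(1, "mode", self.mode)
        return df


def _rep_quantities(rep: GerminationReplicate) -> dict[str, float | None]:
    has_lengths = len(rep.root_lengths) > 0 and len(rep.shoot_lengths) > 0
    return {
        "Eg": None if rep.n_germ_energy is None else germination_energy(rep),
        "G": germination_rate(rep),
        "RL": mean_length(rep.root_lengths) if rep.root_lengths else None,
        "SL": mean_length(rep.shoot_lengths) if rep.shoot_lengths else None,
        "germ": float(rep.n_germ_final),
        "has_lengths": has_lengths,
    }


def _summarise(values: list[float | None], name: str) -> IndexSummary:
    present = [v for v in values if v is not None]
    if not present:
        return IndexSummary(mean=math.nan, sd=None, n=0)
    sd = float(np.std(present, ddof=1)) if len(present) > 1 else 0.0
    return IndexSummary(mean=float(np.mean(present)), sd=sd, n=len(present))


def compute_group_indices(
    group: Sequence[GerminationReplicate],
    control: Sequence[GerminationReplicate],
    mode: Literal["per_replicate", "pooled"] = "per_replicate",
) -> GerminationIndices:
    """All nine indices of a group relative to its control.

    per_replicate (default): each index is computed per dish against the
    control group's mean quantities, then averaged with SD — this is how
    mean ± SD tables are produced.  pooled: one value per index from
    group-level totals/means, SD absent.

    When ``group`` *is* the control (same dishes), the relative indices
    are fixed at their defining values — RRG = RSG = PI = 100 per dish,
    GI = G — since a control compared to itself is the reference, not an
    estimate of it.  Dishes with no measured seedlings contribute to the
    count-based indices but are skipped (and logged) for length-based
    ones.
    """
    if not group or not control:
        raise EmptyGroupError("group and control must be non-empty")
    is_self = list(group) == list(control)

    ctrl_q = [_rep_quantities(r) for r in control]
    ctrl_rl = [q["RL"] for q in ctrl_q if q["RL"] is not None]
    ctrl_sl = [q["SL"] for q in ctrl_q if q["SL"] is not None]
    if not ctrl_rl or not ctrl_sl:
        raise InvalidControlError("control group has no measured seedlings")
    ctrl_mean_rl = float(np.mean(ctrl_rl))
    ctrl_mean_sl = float(np.mean(ctrl_sl))
    ctrl_mean_germ = float(np.mean([q["germ"] for q in ctrl_q]))
    ctrl_mean_g = float(np.mean([q["G"] for q in ctrl_q]))
    if not ctrl_mean_rl > 0:
        raise InvalidControlError("control mean root length is zero")

    condition = group[0].condition

    if mode == "pooled":
        total_seeds = sum(r.n_seeds for r in group)
        energy_counts = [r.n_germ_energy for r in group]
        total_germ = sum(r.n_germ_final for r in group)
        all_rl = [v for r in group for v in r.root_lengths]
        all_sl = [v for r in group for v in r.shoot_lengths]
        g = 100.0 * total_germ / total_seeds
        eg = (
            None
            if any(c is None for c in energy_counts)
            else 100.0 * sum(energy_counts) / total_seeds
        )
        rl = mean_length(all_rl) if all_rl else math.nan
        sl = mean_length(all_sl) if all_sl else math.nan
        ctrl_total_germ = float(sum(r.n_germ_final for r in control))
        ctrl_pool_rl = mean_length([v for r in control for v in r.root_lengths])
        ctrl_pool_sl = mean_length([v for r in control for v in r.shoot_lengths])
        ctrl_pool_g = 100.0 * ctrl_total_germ / sum(r.n_seeds for r in control)
        if is_self:
            rrg = rsg = pi = 100.0
            gi = g
        else:
            rrg = relative_root_growth(rl, ctrl_pool_rl)
            rsg = relative_seed_germination(total_germ, ctrl_total_germ)
            gi = germination_index(g, rrg)
            pi = aerial_influence_index(g, sl, ctrl_pool_g, ctrl_pool_sl)
        vi = vigor_index(g, rl, sl)
        values = {
            "Eg": IndexSummary(math.nan if eg is None else eg, None, len(group)),
            "G": IndexSummary(g, None, len(group)),
            "RL": IndexSummary(rl, None, len(group)),
            "SL": IndexSummary(sl, None, len(group)),
            "RRG": IndexSummary(rrg, None, len(group)),
            "RSG": IndexSummary(rsg, None, len(group)),
            "GI": IndexSummary(gi, None, len(group)),
            "VI": IndexSummary(vi, None, len(group)),
            "PI": IndexSummary(pi, None, len(group)),
        }
        return GerminationIndices(condition=condition, mode=mode, values=values)

    if mode != "per_replicate":
        raise InvalidInputError(f"unknown mode {mode!r}")

    per: dict[str, list[float | None]] = {k: [] for k in INDEX_NAMES}
    for rep in group:
        q = _rep_quantities(rep)
        per["Eg"].append(q["Eg"])
        per["G"].append(q["G"])
        per["RL"].append(q["RL"])
        per["SL"].append(q["SL"])
        if not q["has_lengths"]:
            logger.info(
                "replicate %s/%s has no measured seedlings: skipped for "
                "length-based indices",
                rep.condition,
                rep.replicate_id,
            )
        if is_self:
            rrg = rsg = pi = 100.0
            gi = q["G"]
        else:
            rrg = (
                relative_root_growth(q["RL"], ctrl_mean_rl)
                if q["RL"] is not None
                else None
            )
            rsg = relative_seed_germination(q["germ"], ctrl_mean_germ)
            gi = germination_index(q["G"], rrg) if rrg is not None else None
            pi = (
                aerial_influence_index(q["G"], q["SL"], ctrl_mean_g, ctrl_mean_sl)
                if q["SL"] is not None
                else None
            )
        per["RRG"].append(rrg)
        per["RSG"].append(rsg)
        per["GI"].append(gi)
        per["PI"].append(pi)
        per["VI"].append(
            vigor_index(q["G"], q["RL"], q["SL"])
            if q["has_lengths"]
            else (0.0 if rep.n_germ_final == 0 else None)
        )

    values = {k: _summarise(v, k) for k, v in per.items()}
    return GerminationIndices(condition=condition, mode=mode, values=values)
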