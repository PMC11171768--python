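"""CSV readers and writers for the assay record types.

All files are UTF-8, comma-delimited, dot-decimal, with a header row.
Length lists (root/shoot lengths per dish) are semicolon-separated
decimals in a single cell.  Readers validate row by row and raise a
single :class:`DataValidationError` naming every offending line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .dose_response import DoseGroup
from .errors import DataValidationError, EcotoxError
from .germination import GerminationReplicate
from .membrane import HemolysisSample, LeakageTrace, ViabilityRecord

__all__ = [
    "read_germination_csv",
    "write_germination_csv",
    "read_mortality_csv",
    "write_mortality_csv",
    "read_hemolysis_csv",
    "write_hemolysis_csv",
    "read_viability_csv",
    "write_viability_csv",
    "read_leakage_csv",
    "write_leakage_csv",
]

GERMINATION_COLUMNS = [
    "condition",
    "concentration_ug_ml",
    "replicate",
    "n_seeds",
    "n_germ_energy",
    "n_germ_final",
    "root_lengths",
    "shoot_lengths",
]
MORTALITY_COLUMNS = ["concentration_ug_ml", "replicate", "time_h", "n_total", "n_dead_cum"]
HEMOLYSIS_COLUMNS = ["concentration_ug_ml", "replicate", "a_sample", "a_control", "a_100"]
VIABILITY_COLUMNS = ["cell_line", "concentration_ug_ml", "replicate", "absorbance", "is_control"]
LEAKAGE_COLUMNS = ["fraction_label", "time_s", "fluorescence", "f0", "f_total"]


def _load(path: str | Path, expected: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    return df


def _parse_rows(df: pd.DataFrame, build) -> list:
    """Apply ``build`` per row, collecting errors with 1-based data line numbers."""
    records, problems = [], []
    for i, row in df.iterrows():
        try:
            records.append(build(row))
        except (EcotoxError, ValueError) as exc:
            problems.append(f"  line {i + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise DataValidationError(f"{len(problems)} invalid row(s)", problems)
    return records


def _float_list(cell: str) -> tuple[float, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(float(v) for v in cell.split(";"))


def read_germination_csv(path: str | Path) -> list[GerminationReplicate]:
    df = _load(path, GERMINATION_COLUMNS)

    def build(row) -> GerminationReplicate:
        conc = row["concentration_ug_ml"].strip()
        energy = row["n_germ_energy"].strip()
        return GerminationReplicate(
            condition=row["condition"],
            concentration=float(conc) if conc else None,
            replicate_id=row["replicate"],
            n_seeds=int(row["n_seeds"]),
            n_germ_energy=int(energy) if energy else None,
            n_germ_final=int(row["n_germ_final"]),
            root_lengths=_float_list(row["root_lengths"]),
            shoot_lengths=_float_list(row["shoot_lengths"]),
        )

    return _parse_rows(df, build)


def write_germination_csv(reps: Sequence[GerminationReplicate], path: str | Path) -> None:
    rows = [
        {
            "condition": r.condition,
            "concentration_ug_ml": "" if r.concentration is None else repr(r.concentration),
            "replicate": r.replicate_id,
            "n_seeds": r.n_seeds,
            "n_germ_energy": "" if r.n_germ_energy is None else r.n_germ_energy,
            "n_germ_final": r.n_germ_final,
            "root_lengths": ";".join(repr(v) for v in r.root_lengths),
            "shoot_lengths": ";".join(repr(v) for v in r.shoot_lengths),
        }
        for r in reps
    ]
    pd.DataFrame(rows, columns=GERMINATION_COLUMNS).to_csv(path, index=False)


def read_mortality_csv(path: str | Path) -> list[DoseGroup]:
    df = _load(path, MORTALITY_COLUMNS)

    def build(row) -> DoseGroup:
        rid = row["replicate"].strip()
        return DoseGroup(
            concentration=float(row["concentration_ug_ml"]),
            n_total=int(row["n_total"]),
            n_dead=int(row["n_dead_cum"]),
            time_h=float(row["time_h"]),
            replicate_id=rid or None,
        )

    return _parse_rows(df, build)


def write_mortality_csv(groups: Sequence[DoseGroup], path: str | Path) -> None:
    rows = [
        {
            "concentration_ug_ml": repr(g.concentration),
            "replicate": g.replicate_id or "",
            "time_h": repr(g.time_h),
            "n_total": g.n_total,
            "n_dead_cum": g.n_dead,
        }
        for g in groups
    ]
    pd.DataFrame(rows, columns=MORTALITY_COLUMNS).to_csv(path, index=False)


def read_hemolysis_csv(path: str | Path) -> list[HemolysisSample]:
    df = _load(path, HEMOLYSIS_COLUMNS)

    def build(row) -> HemolysisSample:
        return HemolysisSample(
            concentration=float(row["concentration_ug_ml"]),
            replicate_id=row["replicate"],
            a_sample=float(row["a_sample"]),
            a_control=float(row["a_control"]),
            a_100=float(row["a_100"]),
        )

    return _parse_rows(df, build)


def write_hemolysis_csv(samples: Sequence[HemolysisSample], path: str | Path) -> None:
    rows = [
        {
            "concentration_ug_ml": repr(s.concentration),
            "replicate": s.replicate_id,
            "a_sample": repr(s.a_sample),
            "a_control": repr(s.a_control),
            "a_100": repr(s.a_100),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=HEMOLYSIS_COLUMNS).to_csv(path, index=False)


def read_viability_csv(path: str | Path) -> list[ViabilityRecord]:
    df = _load(path, VIABILITY_COLUMNS)

    def build(row) -> ViabilityRecord:
        return ViabilityRecord(
            cell_line=row["cell_line"],
            concentration=float(row["concentration_ug_ml"]),
            replicate_id=row["replicate"],
            absorbance=float(row["absorbance"]),
            is_control=row["is_control"].strip().lower() in ("1", "true", "yes"),
        )

    return _parse_rows(df, build)


def write_viability_csv(records: Sequence[ViabilityRecord], path: str | Path) -> None:
    rows = [
        {
            "cell_line": r.cell_line,
            "concentration_ug_ml": repr(r.concentration),
            "replicate": r.replicate_id,
            "absorbance": repr(r.absorbance),
            "is_control": str(r.is_control).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=VIABILITY_COLUMNS).to_csv(path, index=False)


def read_leakage_csv(path: str | Path) -> list[LeakageTrace]:
    """One trace per distinct fraction_label; f0/f_total repeat per row."""
    df = _load(path, LEAKAGE_COLUMNS)
    traces = []
    problems = []
    for label, sub in df.groupby("fraction_label", sort=False):
        try:
            times = tuple(float(v) for v in sub["time_s"])
            fluor = tuple(float(v) for v in sub["fluorescence"])
            f0 = {float(v) for v in sub["f0"]}
            f_total = {float(v) for v in sub["f_total"]}
            if len(f0) != 1 or len(f_total) != 1:
                raise DataValidationError(
                    f"trace {label!r}: f0/f_total must be constant within a trace"
                )
            traces.append(
                LeakageTrace(
                    fraction_label=str(label),
                    times_s=times,
                    fluorescence=fluor,
                    f0=f0.pop(),
                    f_total=f_total.pop(),
                )
            )
        except (EcotoxError, ValueError) as exc:
            problems.append(f"  trace {label!r}: {exc}")
    if problems:
        raise DataValidationError(f"{len(problems)} invalid trace(s)", problems)
    return traces


def write_leakage_csv(traces: Sequence[LeakageTrace], path: str | Path) -> None:
    rows = [
        {
            "fraction_label": tr.fraction_label,
            "time_s": repr(t),
            "fluorescence": repr(f),
            "f0": repr(tr.f0),
            "f_total": repr(tr.f_total),
        }
        for tr in traces
        for t, f in zip(tr.times_s, tr.fluorescence)
    ]
    pd.DataFrame(rows, columns=LEAKAGE_COLUMNS).to_csv(path, index=False)
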