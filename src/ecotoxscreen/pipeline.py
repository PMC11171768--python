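"""End-to-end screening pipeline: CSVs in, consolidated report out.

Each assay stage is optional; any configured stage runs, logs its
corrections and exclusions, and contributes a block to the report.
The JSON report is written atomically (temp file + rename) and is
byte-identical across reruns on identical inputs: no timestamps are
embedded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import io as eio
from .correlation import correlation_matrix
from .dose_response import (
    classify_clarkson,
    fit_probit_line,
    lc50_by_replicate,
    se_log_lc50,
    validate_mortality_series,
)
from .errors import EcotoxError, InvalidInputError
from .germination import compute_group_indices, exclude_sparse_groups
from .membrane import assay_summary, cf_release_pct, hemolysis_category, hemolysis_pct, viability_pct

__all__ = ["PipelineConfig", "run_pipeline", "render_text_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and knobs for one screening run; unset paths skip the stage."""

    germination_csv: str | None = None
    mortality_csv: str | None = None
    hemolysis_csv: str | None = None
    viability_csv: str | None = None
    leakage_csv: str | None = None
    control_label: str = "control"
    min_germinated: int = 3
    probit_round: int | None = 2
    control_mortality_pct: float = 0.0
    mortality_times_h: tuple[float, ...] = (24.0, 48.0)
    germination_mode: str = "per_replicate"
    correlate_indices: bool = True


def _germination_block(config: PipelineConfig) -> dict[str, Any]:
    reps = eio.read_germination_csv(config.germination_csv)
    retained, excluded = exclude_sparse_groups(reps, config.min_germinated)
    for _, reason in excluded:
        logger.info("germination exclusion: %s", reason)
    control = [r for r in retained if r.concentration is None]
    if not control:
        raise InvalidInputError("no control dishes (empty concentration) found")
    conditions: dict[str, list] = {}
    for r in retained:
        conditions.setdefault(r.condition, []).append(r)
    tables = []
    per_rep_rows = []
    for name, group in conditions.items():
        idx = compute_group_indices(group, control, mode=config.germination_mode)
        tables.append(idx.to_frame())
        # long per-replicate table for downstream correlation
        for rep in group:
            single = compute_group_indices([rep], control, mode="pooled")
            row = {"condition": name, "replicate": rep.replicate_id}
            row.update({k: v.mean for k, v in single.values.items()})
            per_rep_rows.append(row)
    table = pd.concat(tables, ignore_index=True)
    block: dict[str, Any] = {
        "indices": table.to_dict(orient="records"),
        "excluded": [reason for _, reason in excluded],
        "mode": config.germination_mode,
    }
    if config.correlate_indices and len(per_rep_rows) >= 3:
        frame = pd.DataFrame(per_rep_rows).drop(columns=["condition", "replicate"])
        frame = frame.dropna(axis=1, how="all")
        # constant columns cannot be ranked against anything
        frame = frame.loc[:, frame.nunique() > 1]
        if frame.shape[1] >= 2:
            block["spearman"] = correlation_matrix(frame).to_dict(orient="records")
    return block


def _mortality_block(config: PipelineConfig) -> dict[str, Any]:
    groups = eio.read_mortality_csv(config.mortality_csv)
    validate_mortality_series(groups)
    fits = {}
    for t in config.mortality_times_h:
        at_t = [g for g in groups if g.time_h == t]
        if not at_t:
            continue
        fit = fit_probit_line(
            at_t,
            probit_round=config.probit_round,
            control_pct=config.control_mortality_pct,
        )
        if config.control_mortality_pct == 0:
            logger.info("time %s h: control mortality 0%%, Abbott correction skipped", t)
        entry: dict[str, Any] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_value": fit.p_value,
            "log_lc50": fit.log_lc50,
            "lc50_ug_ml": fit.lc50,
            "clarkson": classify_clarkson(fit.lc50) if fit.slope > 0 else None,
            "points": [dataclasses.asdict(p) for p in fit.points],
        }
        n_per_group = at_t[0].n_total
        entry["se_log_lc50"] = se_log_lc50(fit, n_per_group) if fit.slope > 0 else None
        replicate_ids = {g.replicate_id for g in at_t}
        if len(replicate_ids) >= 2 and None not in replicate_ids:
            mean, sd, estimates = lc50_by_replicate(
                at_t,
                probit_round=config.probit_round,
                control_pct=config.control_mortality_pct,
            )
            entry["lc50_by_replicate"] = {"mean": mean, "sd": sd, "estimates": estimates}
        fits[f"{t:g}h"] = entry
    if not fits:
        raise InvalidInputError(
            f"no dose groups at any configured time {config.mortality_times_h}"
        )
    return {"probit_fits": fits}


def _hemolysis_block(config: PipelineConfig) -> dict[str, Any]:
    samples = eio.read_hemolysis_csv(config.hemolysis_csv)
    conc = [s.concentration for s in samples]
    pct = [hemolysis_pct(s) for s in samples]
    summary = assay_summary(conc, pct, level=50.0, response_label="percent hemolysis")
    top = summary.table.loc[summary.table["concentration"].idxmax()]
    return {
        "per_concentration": summary.table.to_dict(orient="records"),
        "line": {"slope": summary.line.slope, "intercept": summary.line.intercept,
                 "r_squared": summary.line.r_squared},
        "hc50_ug_ml": summary.inverted_concentration,
        "extrapolated": summary.extrapolated,
        "category_at_top_dose": hemolysis_category(float(top["mean"])),
    }


def _viability_block(config: PipelineConfig) -> dict[str, Any]:
    records = eio.read_viability_csv(config.viability_csv)
    blocks = {}
    for line_name in sorted({r.cell_line for r in records}):
        recs = [r for r in records if r.cell_line == line_name]
        controls = [r.absorbance for r in recs if r.is_control]
        if not controls:
            raise InvalidInputError(f"cell line {line_name}: no control wells")
        control_mean = float(np.mean(controls))
        treated = [r for r in recs if not r.is_control]
        conc = [r.concentration for r in treated]
        pct = [viability_pct(r.absorbance, control_mean) for r in treated]
        summary = assay_summary(conc, pct, level=50.0, response_label="percent viability")
        blocks[line_name] = {
            "per_concentration": summary.table.to_dict(orient="records"),
            "line": {"slope": summary.line.slope, "intercept": summary.line.intercept,
                     "r_squared": summary.line.r_squared},
            "ic50_ug_ml": summary.inverted_concentration,
            "extrapolated": summary.extrapolated,
        }
    return {"cell_lines": blocks}


def _leakage_block(config: PipelineConfig) -> dict[str, Any]:
    traces = eio.read_leakage_csv(config.leakage_csv)
    endpoints = []
    for tr in traces:
        endpoints.append(
            {
                "fraction_label": tr.fraction_label,
                "endpoint_time_s": tr.times_s[-1],
                "cf_release_pct": cf_release_pct(tr),
            }
        )
    return {"endpoints": endpoints}


_STAGES = {
    "germination": ("germination_csv", _germination_block),
    "brine_shrimp": ("mortality_csv", _mortality_block),
    "hemolysis": ("hemolysis_csv", _hemolysis_block),
    "viability": ("viability_csv", _viability_block),
    "leakage": ("leakage_csv", _leakage_block),
}


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run every configured stage; optionally write report.json/report.txt.

    Returns the report dict.  A failure in any stage raises an
    :class:`EcotoxError` naming the stage.
    """
    report: dict[str, Any] = {
        "package": {"name": "ecotoxscreen", "version": __version__},
        "inputs": {
            key: getattr(config, key)
            for key, _ in _STAGES.values()
            if getattr(config, key) is not None
        },
        "assays": {},
    }
    ran = False
    for stage, (attr, fn) in _STAGES.items():
        if getattr(config, attr) is None:
            continue
        ran = True
        logger.info("running stage %s", stage)
        try:
            report["assays"][stage] = fn(config)
        except EcotoxError as exc:
            raise EcotoxError(f"stage {stage!r} failed: {exc}") from exc
    if not ran:
        raise InvalidInputError("no assay inputs configured")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _atomic_write(out_dir / "report.json", json.dumps(report, indent=2, sort_keys=True))
        _atomic_write(out_dir / "report.txt", render_text_report(report))
    return report


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _fmt(x: Any, nd: int = 2) -> str:
    if isinstance(x, float):
        return "nan" if math.isnan(x) else f"{x:.{nd}f}"
    return str(x)


def render_text_report(report: dict[str, Any]) -> str:
    """Human-readable rendering: 2 decimals for percents, 4 for coefficients."""
    lines = [f"ecotoxscreen screening report (v{report['package']['version']})", ""]
    assays = report["assays"]
    if "germination" in assays:
        lines.append("== Germination indices ==")
        for row in assays["germination"]["indices"]:
            sd = "" if row["sd"] is None else f" ± {_fmt(row['sd'])}"
            lines.append(
                f"  {row['condition']:<16} {row['index']:<4} {_fmt(row['mean'])}{sd} (n={row['n']})"
            )
        for reason in assays["germination"]["excluded"]:
            lines.append(f"  excluded: {reason}")
        lines.append("")
    if "brine_shrimp" in assays:
        lines.append("== Brine-shrimp lethality (probit analysis) ==")
        for t, fit in assays["brine_shrimp"]["probit_fits"].items():
            lines.append(
                f"  {t}: Y = {fit['slope']:.4f}X {fit['intercept']:+.4f}, "
                f"r² = {fit['r_squared']:.4f}, p = {fit['p_value']:.4f}"
            )
            lines.append(
                f"       LC50 = {_fmt(fit['lc50_ug_ml'])} µg/mL "
                f"(log {fit['log_lc50']:.4f}), Clarkson: {fit['clarkson']}"
            )
        lines.append("")
    if "hemolysis" in assays:
        h = assays["hemolysis"]
        flag = " [extrapolated]" if h["extrapolated"] else ""
        lines.append("== Hemolysis ==")
        lines.append(
            f"  line: Y = {h['line']['slope']:.4f}X + {h['line']['intercept']:.4f}; "
            f"HC50 = {_fmt(h['hc50_ug_ml'], 1)} µg/mL{flag}; "
            f"top-dose category: {h['category_at_top_dose']}"
        )
        lines.append("")
    if "viability" in assays:
        lines.append("== Cell viability (MTS) ==")
        for name, blk in assays["viability"]["cell_lines"].items():
            flag = " [extrapolated]" if blk["extrapolated"] else ""
            lines.append(f"  {name}: IC50 = {_fmt(blk['ic50_ug_ml'], 1)} µg/mL{flag}")
        lines.append("")
    if "leakage" in assays:
        lines.append("== Carboxyfluorescein leakage ==")
        for e in assays["leakage"]["endpoints"]:
            lines.append(
                f"  {e['fraction_label']}: {_fmt(e['cf_release_pct'])}% released "
                f"at {e['endpoint_time_s']:g} s"
            )
        lines.append("")
    return "\n".join(lines)
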