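"""File formats: CGM CSV dialect, meal/patient configs, report writing.

The native CGM dialect is a long-format CSV with header
``subject_id,arm,time_min,glucose_mmol_l``, one reading per row.  An
adapter converts FreeStyle Libre exports (device timestamps, historic
glucose) to relative minutes given the meal-start timestamp.  Glucose is
mmol/L end-to-end; mg/dL inputs are converted at the boundary by
dividing by 18.016.

Report files are deterministic: fixed column order, two decimals for
mmol/L quantities and one for percentages, so identical inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import HypoglycemiaTable, PairedComparison
from .meals import MealComposition
from .metrics import CohortSummary, GlycemicSummary
from .trace import GlucoseTrace

CGM_COLUMNS = ["subject_id", "arm", "time_min", "glucose_mmol_l"]
MGDL_PER_MMOLL = 18.016


class ParseError(ValueError):
    """Malformed input file; the message names the offending row."""


def read_cgm_csv(path: str | Path, mgdl: bool = False) -> list[GlucoseTrace]:
    """Read the native CGM CSV dialect into validated traces."""
    df = pd.read_csv(path, dtype={"subject_id": str, "arm": str})
    if list(df.columns) != CGM_COLUMNS:
        raise ParseError(
            f"{path}: header must be {','.join(CGM_COLUMNS)}, got {','.join(df.columns)}"
        )
    for col in ("time_min", "glucose_mmol_l"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric {col} at line {row}")
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["subject_id", "arm", "time_min"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ParseError(f"{path}: duplicate (subject, arm, time) at line {row}")
    if mgdl:
        df["glucose_mmol_l"] = df["glucose_mmol_l"] / MGDL_PER_MMOLL
    traces = []
    for (subject, arm), grp in df.groupby(["subject_id", "arm"], sort=True):
        grp = grp.sort_values("time_min")
        try:
            traces.append(
                GlucoseTrace(
                    times=grp["time_min"].to_numpy(),
                    values=grp["glucose_mmol_l"].to_numpy(),
                    subject_id=str(subject),
                    arm=str(arm),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: trace ({subject}, {arm}): {exc}") from exc
    return traces


def write_cgm_csv(traces: list[GlucoseTrace], path: str | Path) -> None:
    """Write traces in the native dialect (sorted, fixed formatting)."""
    rows = []
    for tr in sorted(traces, key=lambda t: (t.subject_id, t.arm)):
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.subject_id, tr.arm, f"{t:g}", f"{v:.4f}"))
    with open(path, "w", newline="") as fh:
        fh.write(",".join(CGM_COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


def read_libre_export(
    path: str | Path,
    meal_start: str,
    subject_id: str,
    arm: str = "",
    timestamp_col: str = "Device Timestamp",
    glucose_col: str = "Historic Glucose mmol/L",
    timestamp_format: str = "%d-%m-%Y %H:%M",
    horizon_min: float = 300.0,
    mgdl: bool = False,
) -> GlucoseTrace:
    """Convert a FreeStyle Libre export to a relative-minutes trace.

    ``meal_start`` is a timestamp in ``timestamp_format``; readings before
    it or beyond ``horizon_min`` are dropped.
    """
    df = pd.read_csv(path)
    if timestamp_col not in df.columns or glucose_col not in df.columns:
        raise ParseError(
            f"{path}: expected columns {timestamp_col!r} and {glucose_col!r}"
        )
    t0 = datetime.strptime(meal_start, timestamp_format)
    stamps = [datetime.strptime(s, timestamp_format) for s in df[timestamp_col]]
    minutes = np.array([(s - t0).total_seconds() / 60.0 for s in stamps])
    glucose = pd.to_numeric(df[glucose_col], errors="coerce").to_numpy()
    if mgdl:
        glucose = glucose / MGDL_PER_MMOLL
    keep = (minutes >= 0) & (minutes <= horizon_min) & np.isfinite(glucose)
    order = np.argsort(minutes[keep])
    return GlucoseTrace(
        times=minutes[keep][order],
        values=glucose[keep][order],
        subject_id=subject_id,
        arm=arm,
    )


def read_meal_config(path: str | Path) -> dict[str, MealComposition]:
    """Read meal definitions from a JSON file.

    Accepts a single meal object, a list of meal objects, or
    ``{"meals": [...]}``; each object has ``name`` plus gram masses
    ``carb_g``, ``protein_g``, ``fat_g`` and optional ``fiber_g``.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "meals" in data:
        data = data["meals"]
    if isinstance(data, dict):
        data = [data]
    if not data:
        raise ParseError(f"{path}: no meals defined")
    meals = {}
    for obj in data:
        try:
            meal = MealComposition(
                name=obj["name"],
                carb_g=float(obj["carb_g"]),
                protein_g=float(obj["protein_g"]),
                fat_g=float(obj["fat_g"]),
                fiber_g=float(obj.get("fiber_g", 0.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: invalid meal entry {obj!r}: {exc}") from exc
        meals[meal.name] = meal
    return meals


def load_builtin_meals() -> dict[str, MealComposition]:
    """The two shipped test-meal fixtures (NPM and HPFM)."""
    from importlib.resources import files

    with files("postmeal.data").joinpath("meals.json").open() as fh:
        data = json.load(fh)
    return {
        m["name"]: MealComposition(
            m["name"], m["carb_g"], m["protein_g"], m["fat_g"], m.get("fiber_g", 0.0)
        )
        for m in data["meals"]
    }


def read_patient_config(path: str | Path):
    """Read patient insulin parameters from a JSON file."""
    from .dosing import PatientParams

    with open(path) as fh:
        data = json.load(fh)
    try:
        return PatientParams(
            tdd_units=data.get("tdd_units"),
            icr_g_per_unit=data.get("icr_g_per_unit"),
            dose_increment_units=float(data.get("dose_increment_units", 0.0)),
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _fmt(metric: str, value: float) -> str:
    if isinstance(value, float) and np.isnan(value):
        return "NA"
    if metric.endswith("_pct") or metric.startswith("pct"):
        return f"{value:.1f}"
    return f"{value:.2f}"


def write_summaries_tsv(summaries: list[GlycemicSummary], path: str | Path) -> None:
    """Per-trace outcome table, one row per (subject, arm)."""
    summaries = sorted(summaries, key=lambda s: (s.subject_id, s.arm))
    if not summaries:
        with open(path, "w") as fh:
            fh.write("subject_id\tarm\n")
        return
    metrics = list(summaries[0].scalars())
    with open(path, "w") as fh:
        fh.write("subject_id\tarm\t" + "\t".join(metrics) + "\n")
        for s in summaries:
            vals = s.scalars()
            fh.write(
                s.subject_id
                + "\t"
                + s.arm
                + "\t"
                + "\t".join(_fmt(m, vals[m]) for m in metrics)
                + "\n"
            )


def write_cohort_tsv(cohort: CohortSummary, path: str | Path) -> None:
    """Arm-by-metric mean ± SE table."""
    arms = sorted({arm for arm, _ in cohort.metrics.columns})
    with open(path, "w") as fh:
        fh.write("metric\t" + "\t".join(f"{a}_mean\t{a}_se" for a in arms) + "\n")
        for metric in cohort.metrics.index:
            cells = []
            for a in arms:
                cells.append(_fmt(metric, cohort.metrics.loc[metric, (a, "mean")]))
                cells.append(_fmt(metric, cohort.metrics.loc[metric, (a, "se")]))
            fh.write(metric + "\t" + "\t".join(cells) + "\n")


def write_comparisons_tsv(
    comparisons: dict[str, list[PairedComparison]], path: str | Path
) -> None:
    """Paired CC-vs-FPU comparison table per meal type."""
    header = (
        "meal_type\tmetric\tcc_mean\tcc_se\tfpu_mean\tfpu_se\t"
        "mean_diff\tstatistic\tp_value\tn_pairs\tn_excluded\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for meal_type in sorted(comparisons):
            for c in comparisons[meal_type]:
                fh.write(
                    "\t".join(
                        [
                            meal_type,
                            c.metric,
                            _fmt(c.metric, c.mean_a),
                            _fmt(c.metric, c.se_a),
                            _fmt(c.metric, c.mean_b),
                            _fmt(c.metric, c.se_b),
                            _fmt(c.metric, c.mean_diff),
                            "NA" if np.isnan(c.statistic) else f"{c.statistic:.4f}",
                            "NA" if np.isnan(c.p_value) else f"{c.p_value:.4f}",
                            str(c.n_pairs),
                            str(c.n_excluded),
                        ]
                    )
                    + "\n"
                )


def write_hypoglycemia_tsv(table: HypoglycemiaTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("arm\tn\tn_with_episode\tpct_with_episode\n")
        for row in table.rows:
            fh.write(
                f"{row.arm}\t{row.n}\t{row.n_with_episode}\t{row.pct_with_episode:.1f}\n"
            )
        for meal_type in sorted(table.p_values):
            fh.write(f"# McNemar-exact p ({meal_type}, CC vs FPU): "
                     f"{table.p_values[meal_type]:.4f}\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(data: dict, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(data), fh, indent=1, sort_keys=True)
        fh.write("\n")


def comparisons_to_dict(comparisons: dict[str, list[PairedComparison]]) -> dict:
    return {
        meal: [asdict(c) for c in comps] for meal, comps in comparisons.items()
    }
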