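"""Record, profile and result persistence in tidy text formats.

Layout for a cohort directory: one subdirectory per patient containing
``bg.csv`` (time_min, bg_mmol_L), ``insulin.csv`` (time_min, rate_U_h),
``nutrition.csv`` (time_min, rate_mmol_min) and ``meta.json`` (patient id,
span, weight, provenance).  Insulin and nutrition rows are piecewise-constant
segment starts; the segment runs to the next row or the span end.  Times are
integer-friendly minute offsets from stay start (no datetimes); BG persists
in mmol/L only — mg/dL columns are converted once at ingest when enabled.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .identify import PatientRecord, SIProfile
from .model import MGDL_PER_MMOL, PiecewiseConstant
from .trial import TrialResult


def _require_columns(df: pd.DataFrame, cols, path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"found {list(df.columns)}")


def _read_piecewise(path: Path, value_col: str, t_start: float, t_end: float
                    ) -> PiecewiseConstant:
    if not path.exists():
        raise SchemaError(f"missing stream file {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_min", value_col], path)
    if df.empty:
        raise SchemaError(f"{path}: no rows")
    times = df["time_min"].to_numpy(dtype=float)
    vals = df[value_col].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SchemaError(f"{path}: time_min must be strictly increasing")
    if times[0] > t_start:
        raise SchemaError(f"{path}: first row at {times[0]} min starts after "
                          f"the span start {t_start}")
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~(np.isfinite(vals) & (vals >= 0)))[0])
        raise SchemaError(f"{path}: row {bad + 2}: rates must be finite "
                          "and >= 0")
    return PiecewiseConstant(times, vals, max(t_end, times[-1]))


def read_patient_record(patient_dir: str | Path,
                        convert_mg_dl: bool = False) -> PatientRecord:
    """Read one patient directory into a validated :class:`PatientRecord`."""
    d = Path(patient_dir)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("patient_id", "t_start_min", "t_end_min"):
        if key not in meta:
            raise SchemaError(f"{meta_path}: missing key {key!r}")
    t0, t1 = float(meta["t_start_min"]), float(meta["t_end_min"])

    bg_path = d / "bg.csv"
    if not bg_path.exists():
        raise SchemaError(f"missing stream file {bg_path}")
    bg = pd.read_csv(bg_path, float_precision="round_trip")
    if "bg_mg_dl" in bg.columns and "bg_mmol_L" not in bg.columns:
        if not convert_mg_dl:
            raise SchemaError(
                f"{bg_path}: BG is in mg/dL; pass convert_mg_dl=True to "
                "convert at ingest")
        bg["bg_mmol_L"] = bg["bg_mg_dl"] / MGDL_PER_MMOL
    _require_columns(bg, ["time_min", "bg_mmol_L"], bg_path)

    return PatientRecord(
        patient_id=str(meta["patient_id"]),
        bg_times=bg["time_min"].to_numpy(dtype=float),
        bg_values=bg["bg_mmol_L"].to_numpy(dtype=float),
        insulin=_read_piecewise(d / "insulin.csv", "rate_U_h", t0, t1),
        carb=_read_piecewise(d / "nutrition.csv", "rate_mmol_min", t0, t1),
        t_start=t0, t_end=t1,
        weight=meta.get("weight_kg"),
        provenance=meta.get("provenance", "clinical"),
    )


def read_patient_records(cohort_dir: str | Path,
                         convert_mg_dl: bool = False) -> list[PatientRecord]:
    """Read every patient subdirectory of a cohort directory, sorted by name."""
    root = Path(cohort_dir)
    if not root.is_dir():
        raise SchemaError(f"{root} is not a directory")
    dirs = sorted(p for p in root.iterdir()
                  if p.is_dir() and (p / "meta.json").exists())
    if not dirs:
        raise SchemaError(f"{root}: no patient directories with meta.json")
    return [read_patient_record(p, convert_mg_dl=convert_mg_dl) for p in dirs]


def write_patient_record(record: PatientRecord, patient_dir: str | Path
                         ) -> None:
    d = Path(patient_dir)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_min": record.bg_times,
                  "bg_mmol_L": record.bg_values}).to_csv(
        d / "bg.csv", index=False, float_format="%.17g")
    pd.DataFrame({"time_min": record.insulin.times,
                  "rate_U_h": record.insulin.values}).to_csv(
        d / "insulin.csv", index=False, float_format="%.17g")
    pd.DataFrame({"time_min": record.carb.times,
                  "rate_mmol_min": record.carb.values}).to_csv(
        d / "nutrition.csv", index=False, float_format="%.17g")
    (d / "meta.json").write_text(json.dumps({
        "patient_id": record.patient_id,
        "t_start_min": record.t_start,
        "t_end_min": record.t_end,
        "weight_kg": record.weight,
        "provenance": record.provenance,
    }, indent=2))


def write_patient_records(records, cohort_dir: str | Path) -> None:
    root = Path(cohort_dir)
    root.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_patient_record(rec, root / rec.patient_id)


def write_si_profile(profile: SIProfile, path: str | Path) -> None:
    edges = np.append(profile.breaks, profile.end)
    pd.DataFrame({
        "t_start_min": edges[:-1], "t_end_min": edges[1:],
        "si": profile.values, "status": profile.statuses,
    }).to_csv(path, index=False, float_format="%.17g")


def read_si_profile(path: str | Path) -> SIProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t_start_min", "t_end_min", "si", "status"],
                     Path(path))
    return SIProfile(breaks=df["t_start_min"].to_numpy(dtype=float),
                     values=df["si"].to_numpy(dtype=float),
                     statuses=df["status"].astype(str).tolist(),
                     end=float(df["t_end_min"].iloc[-1]))


def write_trial_result(result: TrialResult, out_dir: str | Path) -> None:
    """Trace and log CSVs plus a JSON summary for one virtual trial."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_min": result.trace_t,
                  "G_mmol_L": result.trace_G}).to_csv(
        d / "trace.csv", index=False, float_format="%.17g")
    pd.DataFrame({
        "time_min": [iv.t for iv in result.interventions],
        "rate_U_h": [iv.rate_U_h for iv in result.interventions],
        "bolus_g": [iv.bolus_g for iv in result.interventions],
        "call_physician": [iv.call_physician for iv in result.interventions],
        "interval_h": [iv.interval_h for iv in result.interventions],
    }).to_csv(d / "interventions.csv", index=False, float_format="%.17g")
    pd.DataFrame({"time_min": result.meas_t,
                  "bg_mmol_L": result.meas_bg}).to_csv(
        d / "measurements.csv", index=False, float_format="%.17g")
    s = result.patient_stats()
    (d / "summary.json").write_text(json.dumps({
        "patient_id": result.patient_id,
        "median_bg_mmol_L": s.median_bg,
        "median_insulin_rate_U_h": s.median_insulin_rate,
        "median_glucose_rate_g_h": s.median_glucose_rate,
        "n_measurements": s.n_measurements,
        "measurements_per_day": s.n_measurements / s.stay_days,
        "total_insulin_U": result.total_insulin_U(),
    }, indent=2))
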