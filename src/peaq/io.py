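"""Readers and writers for the on-disk artifacts of the pipeline.

All tabular artifacts are comma-separated UTF-8 CSV with a mandatory
header row and "." decimals; concentrations are serialized in nM, times
in s, light powers in mW (a power-density conversion, when known, rides
along as metadata and is never applied silently).  Structured artifacts
(calibrations, metadata sidecars, reports) are JSON with a semantic
``schema_version`` field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, HillFit
from .schedule import IlluminationEvent, IlluminationSchedule
from .simulate import TraceSet

SCHEMA_VERSION = "1.0.0"

TRACE_COLUMNS = ["cell_id", "frame", "time_s", "cycle_id", "fluorescence",
                 "background"]
SCHEDULE_COLUMNS = ["event_index", "channel", "intensity_mW", "duration_s",
                    "camera_read", "cycle_id"]


class IOValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trace sets
# ---------------------------------------------------------------------------

def write_trace_csv(trace: TraceSet, path) -> None:
    df = trace.frames.copy()
    df["background"] = np.asarray(trace.background)[df["frame"].to_numpy()]
    df.to_csv(path, index=False, columns=TRACE_COLUMNS)


def write_trace_metadata(trace: TraceSet, path) -> None:
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": trace.seed,
        "expression_scales": trace.expression_scales,
        "background_corrected": trace.background_corrected,
        "fingerprint": trace.fingerprint,
        "metadata": trace.metadata,
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_trace_csv(path, metadata_path=None) -> TraceSet:
    """Read and validate a long-format trace CSV.

    Rows may appear in any order; they are canonically sorted by cell and
    frame.  Missing columns, non-monotone time within a cell, and ragged
    cells (unequal frame counts) are rejected with descriptive errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise IOValidationError(
            f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values(["cell_id", "frame"]).reset_index(drop=True)
    df["cycle_id"] = df["cycle_id"].astype("Int64")

    sizes = df.groupby("cell_id").size()
    if sizes.nunique() > 1:
        raise IOValidationError(
            f"{path}: ragged cells (frame counts {dict(sizes)})")
    for cid, sub in df.groupby("cell_id"):
        t = sub["time_s"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = sub.index[bad[0] + 1]
            raise IOValidationError(
                f"{path}: non-monotone time for cell {cid} at row {row + 2}")

    first = df[df["cell_id"] == df["cell_id"].iloc[0]]
    background = first["background"].to_numpy(dtype=float)

    meta: dict = {}
    fingerprint = None
    seed = None
    corrected = False
    scales: dict[str, float] = {}
    if metadata_path is not None and Path(metadata_path).exists():
        meta = json.loads(Path(metadata_path).read_text())
        seed = meta.get("seed")
        corrected = bool(meta.get("background_corrected", False))
        fingerprint = meta.get("fingerprint")
        scales = meta.get("expression_scales", {})

    ts = TraceSet(
        frames=df[["cell_id", "frame", "time_s", "cycle_id", "fluorescence"]],
        background=background, expression_scales=scales, seed=seed,
        fingerprint=fingerprint, background_corrected=corrected,
        metadata=meta.get("metadata", {}))
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def write_schedule_csv(schedule: IlluminationSchedule, path) -> None:
    rows = []
    for i, ev in enumerate(schedule.events):
        rows.append({
            "event_index": i, "channel": ev.channel,
            "intensity_mW": ev.intensity_mW, "duration_s": ev.duration_s,
            "camera_read": ev.camera_read,
            "cycle_id": ev.cycle_id if ev.cycle_id is not None else "",
        })
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


def read_schedule_csv(path) -> IlluminationSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise IOValidationError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("event_index")
    events = []
    for _, row in df.iterrows():
        cid = row["cycle_id"]
        cycle_id = None if pd.isna(cid) or cid == "" else int(cid)
        events.append(IlluminationEvent(
            channel=str(row["channel"]),
            intensity_mW=float(row["intensity_mW"]),
            duration_s=float(row["duration_s"]),
            camera_read=bool(row["camera_read"]),
            cycle_id=cycle_id))
    return IlluminationSchedule(events)


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

def write_titration_csv(df: pd.DataFrame, path) -> None:
    if "ca_nM" not in df.columns:
        raise IOValidationError("titration table needs a ca_nM column")
    df.to_csv(path, index=False)


def read_titration_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "ca_nM" not in df.columns:
        raise IOValidationError(f"{path}: missing ca_nM column")
    responses = [c for c in ("contrast", "fluorescence") if c in df.columns]
    if not responses and "response" not in df.columns:
        raise IOValidationError(
            f"{path}: need a response column "
            "(contrast, fluorescence, or response)")
    return df


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

def write_calibration_json(curve: CalibrationCurve, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": curve.kind,
        "normalized": curve.normalized,
        "working_fraction": curve.working_fraction,
        "parameters": {
            "f_diff": curve.fit.f_diff, "f_max": curve.fit.f_max,
            "kd": curve.fit.kd, "h": curve.fit.h,
        },
        "stderr": curve.fit.stderr,
        "residual_norm": curve.fit.residual_norm,
        "fingerprint": curve.fingerprint,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_calibration_json(path) -> CalibrationCurve:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version is None or version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise IOValidationError(
            f"{path}: incompatible schema_version {version!r}")
    kind = payload.get("kind")
    if kind not in ("contrast", "fluorescence"):
        raise IOValidationError(f"{path}: invalid kind {kind!r}")
    if payload.get("fingerprint") is None:
        import warnings
        warnings.warn(f"{path}: calibration carries no instrument fingerprint")
    p = payload["parameters"]
    fit = HillFit(f_diff=p["f_diff"], f_max=p["f_max"], kd=p["kd"], h=p["h"],
                  kind=kind, stderr=payload.get("stderr"),
                  residual_norm=payload.get("residual_norm", 0.0))
    return CalibrationCurve(
        fit=fit, normalized=bool(payload.get("normalized", False)),
        working_fraction=float(payload.get("working_fraction", 0.05)),
        fingerprint=payload.get("fingerprint"))


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def write_json_report(report: dict, path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **report}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def config_hash(payload: dict) -> str:
    """Stable hash of a configuration payload for reproducibility logs."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
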