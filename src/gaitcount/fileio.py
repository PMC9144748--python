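"""CSV interchange formats and the model bundle.

Traces travel as plain CSV with integer epoch-ms timestamps:

* acceleration: ``time_ms,x,y,z`` (+ optional ``position`` column holding
  the same tag on every row)
* pressure: ``time_ms,force_n``
* events: ``time_ms``
* window datasets: ``window_start_ms,recording_id,position,label,f0..f59``

Rows are sorted by timestamp on read (with a warning if reordering was
needed) and written at full precision so a write/read round-trip is
lossless.  Fitted models are stored as a versioned joblib bundle;
bundles from a different format version are refused outright.
"""

from __future__ import annotations

import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .traces import AccelTrace, ScalarTrace, StepEvents
from .windows import WindowDataset

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed input files (missing columns, bad cells)."""


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise FormatError(f"{path}: non-numeric value in column {col!r} at line {row}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0]) + 2
            raise FormatError(f"{path}: missing value in column {col!r} at line {row}")
    if not df["time_ms"].is_monotonic_increasing:
        logger.warning("%s: rows out of time order; sorting", path)
        df = df.sort_values("time_ms", kind="stable").reset_index(drop=True)
    return df


def read_accel_csv(path) -> AccelTrace:
    df = _read_csv(path, ["time_ms", "x", "y", "z"])
    position = None
    if "position" in df.columns and df["position"].notna().any():
        position = str(df["position"].iloc[0])
    return AccelTrace(
        t=df["time_ms"].to_numpy(np.int64),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        z=df["z"].to_numpy(float),
        position=position,
    )


def write_accel_csv(trace: AccelTrace, path) -> None:
    df = pd.DataFrame({"time_ms": trace.t, "x": trace.x, "y": trace.y, "z": trace.z})
    if trace.position is not None:
        df["position"] = trace.position
    _atomic_to_csv(df, path)


def read_pressure_csv(path) -> ScalarTrace:
    df = _read_csv(path, ["time_ms", "force_n"])
    return ScalarTrace(
        t=df["time_ms"].to_numpy(np.int64), v=df["force_n"].to_numpy(float), kind="pressure"
    )


def write_pressure_csv(trace: ScalarTrace, path) -> None:
    _atomic_to_csv(pd.DataFrame({"time_ms": trace.t, "force_n": trace.v}), path)


def read_events_csv(path, source: str = "pressure_detected") -> StepEvents:
    df = _read_csv(path, ["time_ms"])
    return StepEvents(times=df["time_ms"].to_numpy(np.int64), source=source)


def write_events_csv(events: StepEvents, path) -> None:
    _atomic_to_csv(pd.DataFrame({"time_ms": events.times}), path)


def read_windows_csv(path, window_s: float = 2.0, overlap_frac: float = 0.5,
                     sample_rate_hz: float = 30.0) -> WindowDataset:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in ("window_start_ms", "position", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return WindowDataset.from_frame(
        df, window_s=window_s, overlap_frac=overlap_frac, sample_rate_hz=sample_rate_hz
    )


def write_windows_csv(dataset: WindowDataset, path) -> None:
    _atomic_to_csv(dataset.to_frame(), path)


def _atomic_to_csv(df: pd.DataFrame, path) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    tmp.replace(path)


def save_model(model, path) -> None:
    """Persist a fitted model as a versioned bundle."""
    path = Path(path)
    bundle = {"format_version": BUNDLE_FORMAT_VERSION, "model": model}
    tmp = path.with_suffix(path.suffix + ".tmp")
    joblib.dump(bundle, tmp)
    tmp.replace(path)


def load_model(path):
    """Load a model bundle, refusing other format versions."""
    bundle = joblib.load(path)
    if not isinstance(bundle, dict) or "format_version" not in bundle:
        raise FormatError(f"{path}: not a gaitcount model bundle")
    if bundle["format_version"] != BUNDLE_FORMAT_VERSION:
        raise FormatError(
            f"{path}: bundle format version {bundle['format_version']} is not supported "
            f"(this build reads version {BUNDLE_FORMAT_VERSION}); retrain instead of migrating"
        )
    return bundle["model"]
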