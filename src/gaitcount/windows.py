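"""Stream alignment and sliding-window dataset construction.

A 2 s window at 30 Hz (60 samples) contains at least one full gait cycle
across the whole walking band; advancing by 50 % of the window (30
samples) doubles the effective dataset size while keeping every interior
step covered by exactly two windows.  Each window pairs the filtered
acceleration-magnitude samples (the feature vector) with the number of
pressure-derived step events falling in the window's half-open time span
(the label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .label import StepEvents, count_events_in
from .traces import AccelTrace, ScalarTrace

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Raised when two streams share no usable time span."""


class InsufficientDataError(ValueError):
    """Raised when a trace is shorter than one analysis window."""


def align_streams(
    accel: AccelTrace, pressure: ScalarTrace, max_skew_ms: int = 50
) -> tuple[AccelTrace, ScalarTrace]:
    """Pair acceleration and pressure samples by nearest timestamp.

    Both traces are trimmed to their overlapping span; each acceleration
    sample is paired with the nearest pressure sample, and pairs whose
    timestamps differ by more than ``max_skew_ms`` are dropped (and
    logged).  The two returned traces have equal length and pairwise skew
    within tolerance.
    """
    if len(accel) == 0 or len(pressure) == 0:
        raise AlignmentError("cannot align an empty trace")
    t_a, t_p = accel.t, pressure.t
    lo = max(t_a[0], t_p[0])
    hi = min(t_a[-1], t_p[-1])
    if lo > hi:
        raise AlignmentError(
            f"no temporal overlap: [{t_a[0]}, {t_a[-1]}] vs [{t_p[0]}, {t_p[-1]}]"
        )
    keep_a = (t_a >= lo) & (t_a <= hi)
    idx_a = np.flatnonzero(keep_a)
    ta = t_a[idx_a]
    # nearest pressure sample for each retained acceleration sample
    pos = np.searchsorted(t_p, ta)
    pos = np.clip(pos, 1, len(t_p) - 1)
    left = t_p[pos - 1]
    right = t_p[pos]
    nearest = np.where(ta - left <= right - ta, pos - 1, pos)
    skew = np.abs(t_p[nearest] - ta)
    ok = skew <= max_skew_ms
    n_drop = int(np.sum(~ok))
    if n_drop:
        logger.info("align_streams: dropped %d pairs with skew > %d ms", n_drop, max_skew_ms)
    idx_a = idx_a[ok]
    idx_p = nearest[ok]
    if idx_a.size == 0:
        raise AlignmentError("all sample pairs exceeded the skew tolerance")
    aligned_accel = AccelTrace(
        t=accel.t[idx_a], x=accel.x[idx_a], y=accel.y[idx_a], z=accel.z[idx_a],
        position=accel.position,
    )
    # keep the acceleration clock for both streams so downstream windows share it
    aligned_pressure = ScalarTrace(t=accel.t[idx_a], v=pressure.v[idx_p], kind=pressure.kind)
    return aligned_accel, aligned_pressure


@dataclass
class WindowDataset:
    """Supervised sliding-window dataset.

    features : (n_windows, window_len) filtered magnitude samples
    labels : per-window step counts (int >= 0)
    positions : per-window carrying-position labels
    window_starts : epoch-ms start time of each window
    recording_ids : integer id of the source recording per window
    """

    features: np.ndarray
    labels: np.ndarray
    positions: np.ndarray
    window_starts: np.ndarray
    recording_ids: np.ndarray = None  # type: ignore[assignment]
    window_s: float = 2.0
    overlap_frac: float = 0.5
    sample_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.positions = np.asarray(self.positions, dtype=object)
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        if self.recording_ids is None:
            self.recording_ids = np.zeros(len(self.labels), dtype=int)
        self.recording_ids = np.asarray(self.recording_ids, dtype=int)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.positions) == len(self.window_starts) == len(self.recording_ids) == n):
            raise ValueError("inconsistent window-dataset field lengths")
        if np.any(self.labels < 0):
            raise ValueError("window labels must be non-negative")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def window_len(self) -> int:
        return int(round(self.window_s * self.sample_rate_hz))

    @property
    def stride(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap_frac)))

    def subset(self, idx) -> "WindowDataset":
        idx = np.asarray(idx)
        return WindowDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            positions=self.positions[idx],
            window_starts=self.window_starts[idx],
            recording_ids=self.recording_ids[idx],
            window_s=self.window_s,
            overlap_frac=self.overlap_frac,
            sample_rate_hz=self.sample_rate_hz,
        )

    @classmethod
    def concatenate(cls, parts: list["WindowDataset"]) -> "WindowDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if (p.window_s, p.overlap_frac, p.sample_rate_hz) != (
                first.window_s, first.overlap_frac, first.sample_rate_hz
            ):
                raise ValueError("window geometry differs between parts")
        return cls(
            features=np.vstack([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            positions=np.concatenate([p.positions for p in parts]),
            window_starts=np.concatenate([p.window_starts for p in parts]),
            recording_ids=np.concatenate([p.recording_ids for p in parts]),
            window_s=first.window_s,
            overlap_frac=first.overlap_frac,
            sample_rate_hz=first.sample_rate_hz,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"f{i}": self.features[:, i] for i in range(self.features.shape[1])}
        return pd.DataFrame(
            {
                "window_start_ms": self.window_starts,
                "recording_id": self.recording_ids,
                "position": self.positions,
                "label": self.labels,
                **cols,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, window_s: float = 2.0, overlap_frac: float = 0.5,
        sample_rate_hz: float = 30.0,
    ) -> "WindowDataset":
        fcols = sorted(
            (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        return cls(
            features=df[fcols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            positions=df["position"].to_numpy(dtype=object),
            window_starts=df["window_start_ms"].to_numpy(dtype=np.int64),
            recording_ids=(
                df["recording_id"].to_numpy(dtype=int)
                if "recording_id" in df else None
            ),
            window_s=window_s,
            overlap_frac=overlap_frac,
            sample_rate_hz=sample_rate_hz,
        )


def window_starts_for(n_samples: int, window_len: int, stride: int) -> np.ndarray:
    """Start indices of full windows: multiples of the stride, partials dropped."""
    if n_samples < window_len:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - window_len + 1, stride)


def slide_features(
    magnitude: ScalarTrace, window_s: float = 2.0, overlap_frac: float = 0.5,
    sample_rate_hz: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix plus per-window start/end times (no labels).

    Returns ``(features, start_ms, end_ms)`` where each window's span is
    half-open ``[start_ms, end_ms)``; the end of window ``w`` is the
    timestamp of the first sample after it (nominal spacing is used past
    the end of the trace).
    """
    window_len = int(round(window_s * sample_rate_hz))
    stride = int(round(window_len * (1.0 - overlap_frac)))
    if stride < 1:
        raise ValueError("overlap_frac too close to 1: empty stride")
    n = len(magnitude)
    if n < window_len:
        raise InsufficientDataError(
            f"trace has {n} samples; a window needs {window_len}"
        )
    starts = window_starts_for(n, window_len, stride)
    feats = np.stack([magnitude.v[s : s + window_len] for s in starts])
    t = magnitude.t
    dt_ms = int(round(1000.0 / sample_rate_hz))
    start_ms = t[starts]
    end_idx = starts + window_len
    end_ms = np.where(end_idx < n, t[np.minimum(end_idx, n - 1)], t[-1] + dt_ms)
    return feats, start_ms.astype(np.int64), end_ms.astype(np.int64)


def make_windows(
    magnitude: ScalarTrace,
    events: StepEvents,
    position: str,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    sample_rate_hz: float = 30.0,
    recording_id: int = 0,
) -> WindowDataset:
    """Build the supervised dataset for one recording.

    Feature rows are the raw filtered-magnitude samples of each window;
    each label is the number of step events in the window's half-open
    time span.  Trailing partial windows are dropped rather than padded
    (padding would fabricate signal and bias the label downward).
    """
    feats, start_ms, end_ms = slide_features(
        magnitude, window_s=window_s, overlap_frac=overlap_frac, sample_rate_hz=sample_rate_hz
    )
    labels = np.array(
        [count_events_in(events, s, e) for s, e in zip(start_ms, end_ms)], dtype=int
    )
    return WindowDataset(
        features=feats,
        labels=labels,
        positions=np.full(len(labels), position, dtype=object),
        window_starts=start_ms,
        recording_ids=np.full(len(labels), recording_id, dtype=int),
        window_s=window_s,
        overlap_frac=overlap_frac,
        sample_rate_hz=sample_rate_hz,
    )
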