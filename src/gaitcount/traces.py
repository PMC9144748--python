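"""In-memory containers for sensor time series and step events.

All traces carry integer epoch-millisecond timestamps (the acquisition
convention of consumer devices) and numpy arrays for the values.  The
nominal sampling rate throughout the pipeline is 30 Hz, high enough to
cover the 0.5-5 Hz band of human walking and running by a wide Nyquist
margin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

#: Valid smartphone carrying positions.
POSITIONS = ("handheld", "pocket", "handbag")

#: Nominal sampling rate of both sensor streams, Hz.
DEFAULT_SAMPLE_RATE_HZ = 30.0


class TraceError(ValueError):
    """Raised for structurally invalid traces (unsorted, ragged, empty)."""


def _as_time_ms(t) -> np.ndarray:
    t = np.asarray(t, dtype=np.int64)
    if t.ndim != 1:
        raise TraceError("timestamps must be one-dimensional")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise TraceError("timestamps must be strictly increasing")
    return t


@dataclass
class AccelTrace:
    """Tri-axial acceleration recording.

    Parameters
    ----------
    t : array of int
        Epoch-millisecond timestamps, strictly increasing.
    x, y, z : array of float
        Acceleration components in m/s^2, gravity included.
    position : str, optional
        Carrying-position tag (``handheld``, ``pocket`` or ``handbag``)
        when the placement of the phone is known.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    position: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = _as_time_ms(self.t)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise TraceError("t, x, y, z must have equal lengths")
        if self.position is not None and self.position not in POSITIONS:
            raise TraceError(
                f"unknown position {self.position!r}; expected one of {POSITIONS}"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) component matrix."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class ScalarTrace:
    """Single-channel time series: acceleration magnitude or plantar force.

    ``kind`` is either ``"magnitude"`` (m/s^2) or ``"pressure"`` (N).
    """

    t: np.ndarray
    v: np.ndarray
    kind: str = "magnitude"

    def __post_init__(self) -> None:
        self.t = _as_time_ms(self.t)
        self.v = np.asarray(self.v, dtype=float)
        if len(self.v) != len(self.t):
            raise TraceError("t and v must have equal lengths")
        if self.kind not in ("magnitude", "pressure"):
            raise TraceError(f"unknown trace kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.t)

    def with_values(self, v) -> "ScalarTrace":
        return replace(self, v=np.asarray(v, dtype=float))


@dataclass
class StepEvents:
    """Step-event times for one recording.

    ``source`` records provenance: ``pressure_detected`` for events found
    by the threshold detector, ``synthetic_truth`` for simulator ground
    truth.
    """

    times: np.ndarray
    source: str = "pressure_detected"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.times.ndim != 1:
            raise TraceError("event times must be one-dimensional")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise TraceError("event times must be ascending")
        if self.source not in ("pressure_detected", "synthetic_truth"):
            raise TraceError(f"unknown event source {self.source!r}")

    @property
    def count(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.count


def regular_time_ms(n: int, sample_rate_hz: float, start_ms: int = 0) -> np.ndarray:
    """Jitterless epoch-ms timestamps for ``n`` samples at ``sample_rate_hz``."""
    if n < 0 or sample_rate_hz <= 0:
        raise TraceError("need n >= 0 and a positive sampling rate")
    return start_ms + np.round(np.arange(n) * 1000.0 / sample_rate_hz).astype(np.int64)
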