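"""Automatic step labeling from plantar pressure.

A force sensor under the toe sees a pressure pulse during every stance
phase and (near-)zero force during swing, so step events can be read off
the pressure channel directly: each upward crossing of a force threshold
marks a ground contact.  The threshold (30 N, half the sensor's 60 N
range) sits above almost all insole noise, and a refractory period of
0.2 s rejects double-crossings — walking cadence bounds the true interval
between contacts to roughly 0.3-1 s, so anything faster is noise.

These detected events are the training labels for the supervised
step-count models; no manual counting is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import ScalarTrace, StepEvents, TraceError


@dataclass(frozen=True)
class PeakDetectorConfig:
    """Threshold detector settings.

    threshold_n : force threshold in N (default 30, within (0, 60]).
    min_interval_s : refractory period in s (default 0.2); crossings closer
        together than this are discarded as noise.
    """

    threshold_n: float = 30.0
    min_interval_s: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_n <= 60.0):
            raise ValueError("threshold_n must lie in (0, 60] N")
        if self.min_interval_s <= 0.0:
            raise ValueError("min_interval_s must be positive")


def detect_steps(pressure: ScalarTrace, config: PeakDetectorConfig | None = None) -> StepEvents:
    """Detect step events as threshold crossings with a refractory period.

    An event fires at each sample where the force rises from below
    ``threshold_n`` to at or above it, provided at least ``min_interval_s``
    has elapsed since the previous accepted event.  The event time is the
    timestamp of the crossing sample; at 30 Hz the ~33 ms quantisation is
    far below the refractory period, so no sub-sample interpolation is
    done.  The input is expected to be clipped and smoothed
    (:func:`gaitcount.preprocess.preprocess_pressure`).
    """
    if config is None:
        config = PeakDetectorConfig()
    t, v = pressure.t, pressure.v
    if t.size > 1 and np.any(np.diff(t) <= 0):  # defensive; ScalarTrace validates too
        raise TraceError("pressure timestamps must be strictly increasing")
    if len(v) == 0:
        return StepEvents(times=np.empty(0, dtype=np.int64), source="pressure_detected")
    thr = config.threshold_n
    above = v >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:  # trace starts mid-stance: count the initial contact
        crossings = np.concatenate([[0], crossings])
    min_gap_ms = config.min_interval_s * 1000.0
    accepted: list[int] = []
    last_time = -np.inf
    for i in crossings:
        ti = t[i]
        if ti - last_time >= min_gap_ms:
            accepted.append(int(ti))
            last_time = ti
    return StepEvents(times=np.asarray(accepted, dtype=np.int64), source="pressure_detected")


def count_events_in(events: StepEvents, start_ms: int, end_ms: int) -> int:
    """Number of events with time in the half-open interval [start_ms, end_ms).

    Half-open membership means an event sitting exactly on a shared window
    boundary is counted once per disjoint tiling, never twice.
    """
    if start_ms >= end_ms:
        raise ValueError(f"inverted interval: [{start_ms}, {end_ms})")
    times = events.times
    lo = np.searchsorted(times, start_ms, side="left")
    hi = np.searchsorted(times, end_ms, side="left")
    return int(hi - lo)
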