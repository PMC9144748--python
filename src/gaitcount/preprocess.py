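"""Raw-stream preprocessing: magnitude, smoothing, sensor-range clipping.

The pipeline deliberately avoids band-pass filtering and sensor fusion:
the magnitude of the raw acceleration vector (gravity included) removes
the dependence on phone orientation, and a short equal-weight moving
average removes sample-level jitter from both the magnitude and the
plantar-force channel.
"""

from __future__ import annotations

import logging

import numpy as np

from .traces import AccelTrace, ScalarTrace

logger = logging.getLogger(__name__)

#: Force-sensitive-resistor usable range, N.  Readings below the floor are
#: indistinguishable from an unloaded sensor; readings above the ceiling
#: saturate it.
CLIP_LOW_N = 0.5
CLIP_HIGH_N = 60.0


class EmptyTraceError(ValueError):
    """Raised when an operation requires at least one sample."""


def magnitude(accel: AccelTrace) -> ScalarTrace:
    """Euclidean norm of the acceleration vector, sample by sample.

    The signal-vector magnitude sqrt(x^2 + y^2 + z^2) is invariant under
    any rotation of the device frame, which is what makes a single model
    applicable to a phone whose orientation is unknown.

    Raises
    ------
    EmptyTraceError
        If the trace has no samples.
    """
    if len(accel) == 0:
        raise EmptyTraceError("cannot take the magnitude of an empty trace")
    v = np.sqrt(accel.x**2 + accel.y**2 + accel.z**2)
    return ScalarTrace(t=accel.t.copy(), v=v, kind="magnitude")


def moving_average(trace: ScalarTrace, half_width: int = 2) -> ScalarTrace:
    """Equal-weight symmetric moving average.

    Interior samples are averaged with their ``half_width`` nearest
    neighbours on each side (a 5-tap 1/5-weight filter at the default).
    Near the edges the window shrinks symmetrically — sample ``i`` uses
    ``min(half_width, i, n-1-i)`` neighbours per side — so the output has
    the input's length, constants pass through unchanged, and no phantom
    zeros are introduced at the boundaries (zeros there would carve
    spurious troughs into a pressure trace).

    ``half_width=0`` is the identity.
    """
    if half_width < 0:
        raise ValueError("half_width must be non-negative")
    v = trace.v
    n = len(v)
    if n == 0 or half_width == 0:
        return trace.with_values(v.copy())
    out = np.empty_like(v)
    h = half_width
    # interior via cumulative sums, shrinking symmetric windows at the edges
    c = np.concatenate([[0.0], np.cumsum(v)])
    if n >= 2 * h + 1:
        out[h : n - h] = (c[2 * h + 1 :] - c[: n - 2 * h]) / (2 * h + 1)
    edges = [i for i in range(n) if i < h or i >= n - h]
    for i in edges:
        k = min(h, i, n - 1 - i)
        out[i] = v[i - k : i + k + 1].mean()
    return trace.with_values(out)


def clip_pressure(raw: ScalarTrace, low_n: float = CLIP_LOW_N, high_n: float = CLIP_HIGH_N) -> ScalarTrace:
    """Clamp plantar-force readings to the sensor's usable range.

    Values below ``low_n`` (including negatives from ADC noise) are set to
    0 N; values above ``high_n`` saturate at ``high_n``.  Idempotent.
    """
    if raw.kind != "pressure":
        raise ValueError("clip_pressure expects a pressure trace")
    v = raw.v
    if np.any(v < 0):
        logger.debug("clip_pressure: %d negative readings treated as below-range", int(np.sum(v < 0)))
    out = np.where(v < low_n, 0.0, np.minimum(v, high_n))
    return raw.with_values(out)


def preprocess_pressure(raw: ScalarTrace, half_width: int = 2) -> ScalarTrace:
    """Standard pressure conditioning: clip to sensor range, then smooth.

    Clipping models the physical sensor limits and therefore precedes the
    software filter.
    """
    return moving_average(clip_pressure(raw), half_width=half_width)


def preprocess_accel(accel: AccelTrace, half_width: int = 2) -> ScalarTrace:
    """Standard acceleration conditioning: magnitude, then smoothing."""
    return moving_average(magnitude(accel), half_width=half_width)
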