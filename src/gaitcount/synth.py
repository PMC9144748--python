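"""Synthetic walking recordings with known ground-truth step events.

The simulator produces the paired streams the pipeline consumes — a
tri-axial phone acceleration trace and a single-foot plantar-force trace
— for a walker at a chosen cadence and phone carrying position.  It is a
signal-level emulation, not a biomechanical model: each step advances a
quasi-periodic gait phase, the acceleration is gravity plus a small
number of phase-locked harmonics with position-specific amplitudes, and
the pressure channel carries one half-sine stance pulse per step.

Position signatures
-------------------
The three carrying positions are given deliberately distinct, documented
profiles (these are synthetic design choices — real phones differ):

``handheld``
    low-amplitude, smooth oscillation (the arm damps the impact), gravity
    along the screen normal (z).
``pocket``
    high amplitude with a strong second harmonic (thigh rotation plus
    heel-strike transient), gravity roughly along the phone's long axis.
``handbag``
    pendulum-like swing: the step-frequency component is amplitude-
    modulated at half the step rate, gravity along y.

The profiles only need to be statistically separable from the magnitude
signal; a held-out classifier on default cohorts validates that (see the
test suite).

Pressure channel
----------------
Each step contributes a half-sine pulse of peak ``pressure_peak_n``
lasting ~60 % of the gait cycle (the stance fraction of normal walking),
with zero force during swing.  Optional sub-threshold artifacts (< 30 N,
placed away from stance pulses) emulate insole noise without changing
the true count.  Ground truth records every pulse onset, so simulator
labels and pressure peaks coincide one-to-one by construction
(``steps_per_peak`` lets a user reinterpret single-foot peaks as strides;
it scales the reported truth count only, never the signals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .traces import (
    DEFAULT_SAMPLE_RATE_HZ,
    POSITIONS,
    AccelTrace,
    ScalarTrace,
    StepEvents,
    regular_time_ms,
)

GRAVITY_MS2 = 9.81

#: Walking cadence band, Hz (steps per second as labeled by the insole).
STEP_FREQ_MIN_HZ = 0.5
STEP_FREQ_MAX_HZ = 3.0

#: Fraction of the gait cycle the foot is on the ground.
STANCE_FRACTION = 0.6


class ScenarioError(ValueError):
    """Raised for physically invalid scenario parameters."""


@dataclass(frozen=True)
class GaitScenario:
    """Parameters of one synthetic walk.

    Parameters
    ----------
    position : str
        Carrying position: ``handheld``, ``pocket`` or ``handbag``.
    duration_s : float
        Recording length in seconds (> 0).
    step_freq_hz : float
        Mean labeled-step rate, within the walking band [0.5, 3.0] Hz.
    sample_rate_hz : float
        Sensor sampling rate (default 30 Hz for both streams).
    noise_sd : float
        Per-axis Gaussian acceleration noise, m/s^2.
    pressure_peak_n : float
        Stance pulse peak force, N (kept below the 60 N sensor ceiling).
    spurious_noise_rate : float
        Expected sub-threshold pressure artifacts per minute.
    cadence_jitter : float
        Relative SD of the step-to-step interval (quasi-periodicity).
    timestamp_jitter_ms : float
        SD of sampling-time jitter; 0 gives jitterless nominal timestamps.
    steps_per_peak : int
        Labeled steps per single-foot pressure peak (default 1: peaks are
        the labels; 2 reinterprets each peak as a stride).
    seed : int
        RNG seed; identical scenario + seed gives bit-identical output.
    """

    position: str = "handheld"
    duration_s: float = 60.0
    step_freq_hz: float = 1.8
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    noise_sd: float = 0.4
    pressure_peak_n: float = 50.0
    spurious_noise_rate: float = 2.0
    cadence_jitter: float = 0.015
    timestamp_jitter_ms: float = 0.0
    steps_per_peak: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ScenarioError(f"unknown position {self.position!r}")
        if self.duration_s <= 0:
            raise ScenarioError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ScenarioError("sample_rate_hz must be positive")
        if not (STEP_FREQ_MIN_HZ <= self.step_freq_hz <= STEP_FREQ_MAX_HZ):
            raise ScenarioError(
                f"step_freq_hz={self.step_freq_hz} outside the walking band "
                f"[{STEP_FREQ_MIN_HZ}, {STEP_FREQ_MAX_HZ}] Hz"
            )
        if self.noise_sd < 0 or self.pressure_peak_n <= 0:
            raise ScenarioError("noise_sd must be >= 0 and pressure_peak_n > 0")
        if self.spurious_noise_rate < 0:
            raise ScenarioError("spurious_noise_rate must be >= 0")
        if self.steps_per_peak < 1:
            raise ScenarioError("steps_per_peak must be >= 1")


@dataclass
class SyntheticRecording:
    """One simulated walk: paired streams, ground truth and provenance."""

    accel: AccelTrace
    pressure: ScalarTrace
    truth: StepEvents
    scenario: GaitScenario


# amplitude of harmonic k (of the step frequency), per position, m/s^2
_HARMONICS = {
    "handheld": {1: 0.7, 2: 0.12},
    "pocket": {1: 2.4, 2: 1.7, 3: 0.5},
    "handbag": {1: 1.6, 2: 0.35},
}
# pendulum amplitude-modulation depth at half the step frequency
_AM_DEPTH = {"handheld": 0.0, "pocket": 0.0, "handbag": 0.5}
# nominal gravity direction in the device frame
_GRAVITY_AXIS = {
    "handheld": np.array([0.0, 0.0, 1.0]),
    "pocket": np.array([1.0, 0.0, 0.0]),
    "handbag": np.array([0.0, 1.0, 0.0]),
}
# how the oscillation distributes over the device axes (unit-normalised below)
_MOTION_MIX = {
    "handheld": np.array([0.25, 0.2, 1.0]),
    "pocket": np.array([1.0, 0.35, 0.55]),
    "handbag": np.array([0.3, 1.0, 0.45]),
}


def _step_onsets(sc: GaitScenario, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic step onset times in seconds, within the recording."""
    period = 1.0 / sc.step_freq_hz
    onsets = []
    t = rng.uniform(0.05, 0.15) * period
    margin = STANCE_FRACTION * period  # room for the stance pulse
    while t < sc.duration_s - margin:
        onsets.append(t)
        jitter = np.clip(rng.normal(0.0, sc.cadence_jitter), -3 * sc.cadence_jitter, 3 * sc.cadence_jitter)
        t += period * (1.0 + jitter)
    return np.asarray(onsets)


def _gait_phase(t_s: np.ndarray, onsets: np.ndarray, period: float) -> np.ndarray:
    """Piecewise-linear phase: advances 2*pi per step, extrapolated at the ends."""
    if onsets.size == 0:
        return 2 * math.pi * t_s / period
    k = 2 * math.pi * np.arange(onsets.size)
    phase = np.interp(t_s, onsets, k)
    before = t_s < onsets[0]
    after = t_s > onsets[-1]
    phase[before] = k[0] + 2 * math.pi * (t_s[before] - onsets[0]) / period
    phase[after] = k[-1] + 2 * math.pi * (t_s[after] - onsets[-1]) / period
    return phase


def _small_rotation(rng: np.random.Generator, max_angle_rad: float = 0.15) -> np.ndarray:
    """Random small rotation matrix (per-recording device tilt)."""
    angles = rng.uniform(-max_angle_rad, max_angle_rad, size=3)
    cx, sx = math.cos(angles[0]), math.sin(angles[0])
    cy, sy = math.cos(angles[1]), math.sin(angles[1])
    cz, sz = math.cos(angles[2]), math.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _stance_pulses(sc: GaitScenario, t_s: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    period = 1.0 / sc.step_freq_hz
    v = np.zeros_like(t_s)
    stance = STANCE_FRACTION * period
    for onset in onsets:
        in_pulse = (t_s >= onset) & (t_s < onset + stance)
        v[in_pulse] += sc.pressure_peak_n * np.sin(math.pi * (t_s[in_pulse] - onset) / stance)
    return v


def _add_spurious(
    sc: GaitScenario, t_s: np.ndarray, v: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sub-threshold artifacts placed strictly clear of stance pulses."""
    n_art = rng.poisson(sc.spurious_noise_rate * sc.duration_s / 60.0)
    if n_art == 0:
        return v
    dt = 1.0 / sc.sample_rate_hz
    # keep 3 samples clear of any stance support so smoothing cannot merge
    occupied = v > 0
    kernel = 3
    dilated = occupied.copy()
    for s in range(1, kernel + 1):
        dilated[:-s] |= occupied[s:]
        dilated[s:] |= occupied[:-s]
    out = v.copy()
    for _ in range(n_art):
        width_s = rng.uniform(0.05, 0.15)
        amp = rng.uniform(5.0, 25.0)
        for _attempt in range(50):
            center = rng.uniform(0.0, sc.duration_s)
            lo, hi = center - width_s / 2, center + width_s / 2
            idx = np.flatnonzero((t_s >= lo) & (t_s < hi))
            if idx.size == 0:
                continue
            pad_lo = max(idx[0] - kernel, 0)
            pad_hi = min(idx[-1] + kernel + 1, len(v))
            if not dilated[pad_lo:pad_hi].any():
                out[idx] += amp * np.sin(math.pi * (t_s[idx] - lo) / width_s)
                dilated[pad_lo:pad_hi] = True
                break
    return out


def generate_walk(scenario: GaitScenario) -> SyntheticRecording:
    """Simulate one walk; deterministic given the scenario (seed included).

    Returns a :class:`SyntheticRecording` whose acceleration and pressure
    traces cover the same span at the same nominal rate and whose
    ``truth`` lists exactly the stance-pulse onsets synthesised into the
    pressure channel (times in epoch ms).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n = int(round(sc.duration_s * sc.sample_rate_hz))
    if n < 1:
        raise ScenarioError("duration too short for a single sample")
    t_ms = regular_time_ms(n, sc.sample_rate_hz)
    if sc.timestamp_jitter_ms > 0:
        jit = np.round(rng.normal(0.0, sc.timestamp_jitter_ms, size=n)).astype(np.int64)
        t_ms = np.maximum.accumulate(t_ms + jit)  # keep ordering
        t_ms += np.arange(n, dtype=np.int64) * (np.diff(t_ms, prepend=-1) == 0)
    t_s = t_ms / 1000.0

    onsets = _step_onsets(sc, rng)
    period = 1.0 / sc.step_freq_hz
    phase = _gait_phase(t_s, onsets, period)

    # phase-locked oscillation with position-specific harmonic content
    osc = np.zeros(n)
    for k, amp in _HARMONICS[sc.position].items():
        osc += amp * np.sin(k * phase + rng.uniform(0, 2 * math.pi))
    depth = _AM_DEPTH[sc.position]
    if depth > 0:
        osc *= 1.0 + depth * np.sin(phase / 2 + rng.uniform(0, 2 * math.pi))

    mix = _MOTION_MIX[sc.position]
    mix = mix / np.linalg.norm(mix)
    tilt = _small_rotation(rng)
    g_vec = GRAVITY_MS2 * (tilt @ _GRAVITY_AXIS[sc.position])
    mix_vec = tilt @ mix
    xyz = g_vec[None, :] + osc[:, None] * mix_vec[None, :]
    xyz = xyz + rng.normal(0.0, sc.noise_sd, size=(n, 3))
    accel = AccelTrace(t=t_ms, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2], position=sc.position)

    force = _stance_pulses(sc, t_s, onsets)
    force = _add_spurious(sc, t_s, force, rng)
    pressure = ScalarTrace(t=t_ms.copy(), v=force, kind="pressure")

    truth_ms = np.round(onsets * 1000.0).astype(np.int64)
    truth_ms = np.repeat(truth_ms, sc.steps_per_peak) if sc.steps_per_peak > 1 else truth_ms
    truth = StepEvents(times=truth_ms, source="synthetic_truth")
    return SyntheticRecording(accel=accel, pressure=pressure, truth=truth, scenario=sc)


def generate_cohort(scenarios: Sequence[GaitScenario]) -> list[SyntheticRecording]:
    """Simulate one recording per scenario (independent RNG streams per seed)."""
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("generate_cohort needs at least one scenario")
    return [generate_walk(sc) for sc in scenarios]


def default_cohort_scenarios(
    duration_s: float = 420.0,
    step_freqs_hz: Sequence[float] = (1.2, 1.8, 2.4),
    base_seed: int = 0,
) -> list[GaitScenario]:
    """The study-condition cohort: every position at every cadence.

    Three carrying positions x three self-paced cadences, 7 minutes each
    (21 minutes per position), covering the slow-to-brisk walking range.
    Seeds are derived deterministically from ``base_seed``.
    """
    scenarios = []
    i = 0
    for position in POSITIONS:
        for f in step_freqs_hz:
            scenarios.append(
                GaitScenario(
                    position=position,
                    duration_s=duration_s,
                    step_freq_hz=f,
                    seed=(base_seed * 1000 + i) % (2**31 - 1),
                )
            )
            i += 1
    return scenarios
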