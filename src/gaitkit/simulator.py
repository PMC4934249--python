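"""Synthetic insole-gait simulator with exact ground truth.

The simulator builds a closed-form foot trajectory — per stride a smooth
lift-advance-land swing (forward advance: minimum-jerk ramp of the stride
length; vertical: half-sine of the lift height) separated by motionless
stance — samples it at the recording rate, and converts positions to
accelerations by exact backward second differences.  Because the pipeline
integrates with the matching rectangular rule, the double integral of the
noiseless vertical acceleration over a swing reproduces the trajectory's
sampled vertical displacement to machine precision, which is what makes
parameter-recovery tests meaningful: ground truth and pipeline are linked
mathematically, not by construction of independent noise around a
template.

Gravity is injected into the raw signals (so the gravity-separation
recurrence is exercised end to end, not bypassed), followed by optional
white Gaussian sensor noise.  Pressure words follow a four-phase
heel-to-toe activation template during stance (word always above the
segmentation threshold) and are zero during swing except for optional
injected Sensor-8 "slightly pressed" (word == 1) glitches in late swing —
the hardware artifact the threshold rule absorbs.

Defaults emulate the method's study conditions: 50 Hz sampling, 0.4 s
swing / 0.6 s stance (1 s gait cycle), 1.25 m strides giving average
speeds in the observed 1-1.6 m/s band, 5 cm foot lift, and a noise floor
of 0.3 m/s^2 typical of a consumer MEMS accelerometer strapped to a shoe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import LabelledWalk
from .codec import encode_pressure
from .io import InsoleRecording, RecordingMeta

# stance pressure templates: heel strike -> loading/flat -> mid stance -> heel off
# (Sensor 1 = first metatarsal ... Sensor 7-8 = heel)
_STANCE_PATTERNS = [
    encode_pressure([0, 0, 0, 0, 0, 0, 2, 2]),
    encode_pressure([0, 0, 0, 1, 1, 2, 3, 3]),
    encode_pressure([2, 2, 2, 2, 2, 2, 2, 2]),
    encode_pressure([3, 3, 2, 2, 1, 0, 0, 0]),
]
_FLAT_WORD = _STANCE_PATTERNS[2]
_GLITCH_WORD = encode_pressure([0, 0, 0, 0, 0, 0, 0, 1])  # == 1
#: fraction of the swing counted as "late swing" for glitch injection
_LATE_SWING_FRACTION = 0.75


@dataclass
class SimulationSpec:
    """Ground-truth parameters of one synthetic walk."""

    n_strides: int = 12
    stride_length: float = 1.25  # m per stride
    stride_jitter: float = 0.05  # fractional per-stride length jitter
    swing_duration: float = 0.4  # s
    stance_duration: float = 0.6  # s
    lift_height: float = 0.05  # m
    fs: float = 50.0  # Hz
    accel_noise_sd: float = 0.3  # m/s^2 per axis
    pressure_glitch_prob: float = 0.1  # per late-swing sample
    gravity_vector: tuple[float, float, float] = (0.0, 0.0, 9.81)
    seed: int = 0
    #: explicit per-stride lengths; overrides n_strides/stride_length/jitter
    stride_lengths: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_strides < 0:
            raise ValueError(f"n_strides must be >= 0, got {self.n_strides}")
        if self.swing_duration <= 0 or self.stance_duration <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.pressure_glitch_prob <= 1.0:
            raise ValueError("pressure_glitch_prob must be in [0, 1]")
        if not 0.0 <= self.stride_jitter < 1.0:
            raise ValueError("stride_jitter must be in [0, 1)")
        if self.accel_noise_sd < 0:
            raise ValueError("accel_noise_sd must be >= 0")
        if self.stride_lengths is not None and len(self.stride_lengths) != self.n_strides:
            raise ValueError("stride_lengths must have n_strides entries")


@dataclass
class GroundTruth:
    """Exact answers the pipeline should recover from a simulated recording."""

    stride_count: int
    swing_intervals: list[tuple[float, float]]  # (start, stop) seconds
    total_distance: float  # m
    per_stride_ratio: list[float] = field(default_factory=list)  # dMAG/|dz| of the trajectory


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Monotone 0->1 ramp with zero velocity and acceleration at both ends."""
    return s**3 * (10.0 - 15.0 * s + 6.0 * s**2)


def _difference_accel(pos: np.ndarray, fs: float) -> np.ndarray:
    """Exact backward second differences; zero initial velocity."""
    v = np.diff(pos, prepend=pos[0]) * fs
    return np.diff(v, prepend=0.0) * fs


def _double_sum(a: np.ndarray, dt: float) -> float:
    """Rectangular double integral matching the pipeline's quadrature."""
    return float(np.sum(np.cumsum(a) * dt) * dt)


def simulate(spec: SimulationSpec) -> tuple[InsoleRecording, GroundTruth]:
    """Generate one synthetic walk and its ground truth.

    The recording starts and ends in stance.  Fixed seed gives a
    bit-identical recording on repeated calls.
    """
    rng = np.random.default_rng(spec.seed)
    fs, dt = spec.fs, 1.0 / spec.fs
    n_sw = int(round(spec.swing_duration * fs))
    n_st = int(round(spec.stance_duration * fs))
    if n_sw < 2 or n_st < 1:
        raise ValueError("swing/stance durations too short for the sampling rate")

    if spec.stride_lengths is not None:
        lengths = np.asarray(spec.stride_lengths, dtype=float)
    else:
        lengths = spec.stride_length * (
            1.0 + spec.stride_jitter * rng.uniform(-1.0, 1.0, spec.n_strides)
        )

    n = n_st + spec.n_strides * (n_sw + n_st)
    x = np.zeros(n)
    z = np.zeros(n)
    pressure = np.empty(n, dtype=np.int64)

    # lead-in stance: standing flat
    pressure[:n_st] = _FLAT_WORD

    s = np.arange(n_sw) / n_sw  # phase 0 .. (n_sw-1)/n_sw; landing at next stance sample
    ramp = _minimum_jerk(s)
    lift = spec.lift_height * np.sin(np.pi * s)
    stance_words = np.array(
        [_STANCE_PATTERNS[min(3, 4 * j // n_st)] for j in range(n_st)], dtype=np.int64
    )

    swing_intervals: list[tuple[float, float]] = []
    base_x = 0.0
    for i in range(spec.n_strides):
        s0 = n_st + i * (n_sw + n_st)
        x[s0 : s0 + n_sw] = base_x + lengths[i] * ramp
        z[s0 : s0 + n_sw] = lift
        base_x += lengths[i]
        x[s0 + n_sw : s0 + n_sw + n_st] = base_x
        pressure[s0 : s0 + n_sw] = 0
        pressure[s0 + n_sw : s0 + n_sw + n_st] = stance_words
        swing_intervals.append((s0 / fs, (s0 + n_sw) / fs))

    ax = _difference_accel(x, fs)
    az = _difference_accel(z, fs)
    linear = np.column_stack([ax, np.zeros(n), az])

    raw = linear + np.asarray(spec.gravity_vector, dtype=float)
    if spec.accel_noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.accel_noise_sd, size=(n, 3))

    if spec.pressure_glitch_prob > 0:
        late = s >= _LATE_SWING_FRACTION
        for i in range(spec.n_strides):
            s0 = n_st + i * (n_sw + n_st)
            hit = late & (rng.random(n_sw) < spec.pressure_glitch_prob)
            pressure[s0 : s0 + n_sw][hit] = _GLITCH_WORD

    recording = InsoleRecording(
        t=np.arange(n) / fs,
        accel=raw,
        pressure=pressure,
        fs=fs,
        meta=RecordingMeta(subject="synthetic", annotations={"seed": spec.seed}),
    )

    # trajectory-implied ratios from the noiseless linear accelerations
    ratios = []
    for start, stop in ((int(round(a * fs)), int(round(b * fs))) for a, b in swing_intervals):
        a_mag = np.linalg.norm(linear[start:stop], axis=1)
        d_mag = _double_sum(a_mag, dt)
        dz = _double_sum(linear[start:stop, 2], dt)
        ratios.append(d_mag / abs(dz) if dz != 0 else float("nan"))

    truth = GroundTruth(
        stride_count=spec.n_strides,
        swing_intervals=swing_intervals,
        total_distance=float(lengths.sum()),
        per_stride_ratio=ratios,
    )
    return recording, truth


def simulate_database(
    spec_template: SimulationSpec,
    n_walks: int,
    reference_distance: float,
    seed: int,
) -> list[LabelledWalk]:
    """Generate a labelled walking database over a fixed course.

    Every walk covers exactly ``reference_distance`` metres: per-stride
    lengths are jittered around reference/n_strides and renormalised so
    they sum to the reference, the way real strides vary over a fixed
    course.  Per-walk seeds derive deterministically from the master seed.
    """
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    if not reference_distance > 0:
        raise ValueError("reference_distance must be positive")
    nominal = spec_template.n_strides * spec_template.stride_length
    slack = max(spec_template.stride_jitter, 0.15)
    if abs(nominal - reference_distance) > slack * reference_distance:
        raise ValueError(
            f"template covers {nominal:.3g} m but the course is {reference_distance} m; "
            "adjust n_strides/stride_length"
        )
    rng = np.random.default_rng(seed)
    base = reference_distance / spec_template.n_strides
    walks: list[LabelledWalk] = []
    for _ in range(n_walks):
        walk_seed = int(rng.integers(0, 2**31 - 1))
        lengths = base * (
            1.0 + spec_template.stride_jitter * rng.uniform(-1.0, 1.0, spec_template.n_strides)
        )
        lengths *= reference_distance / lengths.sum()
        spec = replace(
            spec_template,
            seed=walk_seed,
            stride_length=base,
            stride_lengths=tuple(lengths),
        )
        recording, _ = simulate(spec)
        walks.append(LabelledWalk(recording=recording, reference_distance=reference_distance))
    return walks
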