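"""Per-stride double integration and cumulative distance estimation.

For each swing phase the acceleration magnitude a[k] = |(ax, ay, az)| and
the vertical component az[k] are double-integrated with the rectangular
(left-endpoint) rule, with velocity reset to zero at swing start — the
zero-velocity-at-stance assumption:

    vMAG[k] = sum_{j<=k} a[j] * dt        dMAG = sum_k vMAG[k] * dt
    vz[k]   = sum_{j<=k} az[j] * dt       dz   = sum_k vz[k] * dt

dMAG is the "tracing displacement" (path-length proxy of the foot's arc in
the air) and dz the vertical displacement.  Their ratio, scaled by a
calibrated coefficient K plus a constant foot length L0 per stride, gives
the per-stride ground distance, accumulated online:

    d[n] = d[n-1] + K * dMAG[n]/|dz[n]| + L0,     d[0] = 0.

|dz| is used because the signed vertical displacement over a lift-and-land
swing can be near zero or negative; strides whose |dz| falls below an
epsilon guard are flagged and fall back to the median ratio of the
unflagged strides in the same recording.  The rectangular rule is kept
deliberately (rather than trapezoidal): K absorbs the quadrature constant,
and like any common gain it cancels from the calibrated estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateVerticalError, NoStridesError
from .segmentation import StrideSegment

#: default guard on |dz| in metres
DZ_EPSILON = 1e-3


@dataclass
class DistanceParams:
    """Calibration coefficient K, constant foot length L0 (m), |dz| guard."""

    K: float = 1.0
    L0: float = 0.26
    dz_epsilon: float = DZ_EPSILON

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if self.L0 < 0:
            raise ValueError(f"L0 must be non-negative, got {self.L0}")
        if not self.dz_epsilon > 0:
            raise ValueError(f"dz_epsilon must be positive, got {self.dz_epsilon}")


@dataclass
class StrideIntegrals:
    """Double-integration products of one swing phase."""

    a_mag: np.ndarray  # per-sample magnitude, m/s^2
    v_mag: np.ndarray  # per-sample speed integral, m/s
    d_mag: float  # tracing displacement, m
    vz: np.ndarray  # per-sample vertical velocity, m/s
    dz: float  # vertical displacement, m (signed)
    ratio: float  # d_mag / |dz|; NaN when flagged
    flagged: bool  # |dz| below the epsilon guard


@dataclass
class StrideDistance:
    """One stride's contribution to the cumulative estimate."""

    segment: StrideSegment
    integrals: StrideIntegrals
    ratio_used: float  # own ratio, or the recording's median when flagged
    cumulative_distance: float  # d[n] in metres


@dataclass
class DistanceEstimate:
    per_stride: list[StrideDistance]
    total_distance: float
    stride_count: int


def mask_acceleration(series: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gate linear acceleration by the swing mask, sample-wise.

    a_hat(k) = F(k) * a(k) per axis: stance samples are zeroed, swing
    samples pass unchanged.
    """
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask)
    if len(series) != len(mask):
        raise ValueError(
            f"series length {len(series)} != mask length {len(mask)}"
        )
    return series * mask[:, None]


def integrate_stride(
    series: np.ndarray,
    segment: StrideSegment,
    fs: float,
    dz_epsilon: float = DZ_EPSILON,
) -> StrideIntegrals:
    """Rectangular double integration of one swing phase.

    ``series`` is the (n, 3) linear (optionally masked) acceleration; the
    integrals run over ``segment``'s samples only, with velocity zeroed at
    swing start.
    """
    series = np.asarray(series, dtype=float)
    if segment.start_idx < 0 or segment.stop_idx > len(series):
        raise ValueError(f"segment [{segment.start_idx}, {segment.stop_idx}) outside series")
    if segment.stop_idx <= segment.start_idx:
        raise ValueError("empty stride segment")
    dt = 1.0 / fs
    window = series[segment.start_idx : segment.stop_idx]
    a_mag = np.linalg.norm(window, axis=1)
    v_mag = np.cumsum(a_mag) * dt
    d_mag = float(np.sum(v_mag) * dt)
    vz = np.cumsum(window[:, 2]) * dt
    dz = float(np.sum(vz) * dt)
    flagged = abs(dz) < dz_epsilon
    ratio = float("nan") if flagged else d_mag / abs(dz)
    return StrideIntegrals(
        a_mag=a_mag, v_mag=v_mag, d_mag=d_mag, vz=vz, dz=dz, ratio=ratio, flagged=flagged
    )


def effective_ratios(
    integrals: list[StrideIntegrals],
) -> list[float]:
    """Per-stride dMAG/|dz| ratios with the median fallback applied.

    Flagged strides (|dz| below the guard) take the median ratio of the
    unflagged strides in the same recording.  Raises
    :class:`DegenerateVerticalError` when every stride is flagged.
    """
    unflagged = [s.ratio for s in integrals if not s.flagged]
    if not unflagged:
        raise DegenerateVerticalError(
            "degenerate vertical displacement: every stride's |dz| is below the guard"
        )
    fallback = float(np.median(unflagged))
    return [s.ratio if not s.flagged else fallback for s in integrals]


def estimate_distance(
    series: np.ndarray,
    segments: list[StrideSegment],
    params: DistanceParams,
    fs: float,
) -> DistanceEstimate:
    """Cumulative walking-distance estimate over all strides.

    Implements the online update d[n] = d[n-1] + K * ratio[n] + L0, which
    is exactly equivalent to the batch form K * sum(ratio) + N * L0.
    """
    if not segments:
        raise NoStridesError("no strides detected")
    integrals = [
        integrate_stride(series, seg, fs, dz_epsilon=params.dz_epsilon) for seg in segments
    ]
    ratios = effective_ratios(integrals)
    per_stride: list[StrideDistance] = []
    d = 0.0
    for seg, intg, r in zip(segments, integrals, ratios):
        d = d + params.K * r + params.L0
        per_stride.append(
            StrideDistance(segment=seg, integrals=intg, ratio_used=r, cumulative_distance=d)
        )
    return DistanceEstimate(
        per_stride=per_stride, total_distance=d, stride_count=len(segments)
    )
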