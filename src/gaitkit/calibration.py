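"""Calibration of the distance coefficient K and its evaluation.

The total-distance estimate is linear in K:

    d_hat = K * sum_n ratio[n] + N * L0,

so the K that makes a labelled walk's estimate equal its reference
distance d_r is the exact algebraic inversion

    K_i = (d_r - N_i * L0) / sum_n ratio[n]_i .

Fitting over a training set takes one K per walk and averages them.
Evaluation follows a leave-one-out protocol: each walk is held out in
turn, K is fitted on the remainder, and the held-out walk's distance is
estimated with that K.  The headline error is the mean relative error

    e = (1/N) * sum_i |d(m)_i - d(r)_i| / d(r)_i

(absolute deviations: per-group error tables are incompatible with signed
means), alongside mean/median/min/max/SD of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceParams
from .exceptions import CalibrationError
from .io import InsoleRecording
from .pipeline import PipelineConfig, measure_walk


@dataclass
class LabelledWalk:
    """A recording paired with the ground-truth distance walked."""

    recording: InsoleRecording
    reference_distance: float

    def __post_init__(self) -> None:
        if not self.reference_distance > 0:
            raise ValueError(
                f"reference_distance must be positive, got {self.reference_distance}"
            )


@dataclass
class CalibrationModel:
    K: float
    per_sample_K: list[float]
    params: DistanceParams


@dataclass
class EvaluationResult:
    """Summary statistics of distance estimates against their references."""

    n: int
    estimates: list[float]
    mean: float
    median: float
    min: float
    max: float
    sd: float
    error: float  # mean relative error, dimensionless
    fold_K: list[float] = field(default_factory=list)


def _walk_label(walk: LabelledWalk, index: int) -> str:
    subject = walk.recording.meta.subject
    return f"walk {index}" + (f" (subject {subject})" if subject else "")


def _summaries(
    walks: list[LabelledWalk], config: PipelineConfig
) -> list[tuple[int, float]]:
    """Per-walk (stride count, sum of effective ratios)."""
    out = []
    for i, walk in enumerate(walks):
        m = measure_walk(walk.recording, config)
        if m.n_strides == 0:
            raise CalibrationError(f"{_walk_label(walk, i)}: no strides detected")
        out.append((m.n_strides, m.sum_ratio))
    return out


def _invert_K(
    walk: LabelledWalk, index: int, n_strides: int, sum_ratio: float, L0: float
) -> float:
    if not sum_ratio > 0:
        raise CalibrationError(
            f"{_walk_label(walk, index)}: non-positive ratio sum {sum_ratio}"
        )
    K = (walk.reference_distance - n_strides * L0) / sum_ratio
    if not K > 0:
        raise CalibrationError(
            f"{_walk_label(walk, index)}: non-positive coefficient K={K:.6g} "
            f"(reference {walk.reference_distance} m vs {n_strides} strides x L0)"
        )
    return K


def fit_K(walks: list[LabelledWalk], config: PipelineConfig) -> CalibrationModel:
    """Fit the coefficient K on a set of labelled walks.

    Each walk contributes the exact K that reproduces its own reference
    distance; the model's K is the arithmetic mean of these.
    """
    if not walks:
        raise CalibrationError("need at least one labelled walk")
    per_sample = [
        _invert_K(w, i, n, s, config.distance.L0)
        for i, (w, (n, s)) in enumerate(zip(walks, _summaries(walks, config)))
    ]
    return CalibrationModel(
        K=float(np.mean(per_sample)), per_sample_K=per_sample, params=config.distance
    )


def error_stats(estimates: list[float], reference: float) -> EvaluationResult:
    """Mean relative error and summary statistics against one common reference."""
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    if not reference > 0:
        raise ValueError(f"reference must be positive, got {reference}")
    est = np.asarray(estimates, dtype=float)
    return EvaluationResult(
        n=len(est),
        estimates=list(map(float, est)),
        mean=float(est.mean()),
        median=float(np.median(est)),
        min=float(est.min()),
        max=float(est.max()),
        sd=float(est.std(ddof=1)) if len(est) > 1 else 0.0,
        error=float(np.mean(np.abs(est - reference) / reference)),
    )


def loocv(walks: list[LabelledWalk], config: PipelineConfig) -> EvaluationResult:
    """Leave-one-out cross-validation of the calibration.

    Deterministic: each walk is measured once, then every fold's K is the
    mean of the other walks' per-sample coefficients.
    """
    if len(walks) < 2:
        raise CalibrationError("leave-one-out needs at least two walks")
    summaries = _summaries(walks, config)
    L0 = config.distance.L0
    per_sample = [
        _invert_K(w, i, n, s, L0)
        for i, (w, (n, s)) in enumerate(zip(walks, summaries))
    ]
    total_K = float(np.sum(per_sample))
    estimates: list[float] = []
    fold_K: list[float] = []
    rel_errors: list[float] = []
    for i, (walk, (n, s)) in enumerate(zip(walks, summaries)):
        K = (total_K - per_sample[i]) / (len(walks) - 1)
        d_hat = K * s + n * L0
        estimates.append(d_hat)
        fold_K.append(K)
        rel_errors.append(abs(d_hat - walk.reference_distance) / walk.reference_distance)
    est = np.asarray(estimates)
    return EvaluationResult(
        n=len(walks),
        estimates=list(map(float, est)),
        mean=float(est.mean()),
        median=float(np.median(est)),
        min=float(est.min()),
        max=float(est.max()),
        sd=float(est.std(ddof=1)),
        error=float(np.mean(rel_errors)),
        fold_K=fold_K,
    )
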