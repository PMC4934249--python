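"""Swing-phase segmentation and stride counting from pressure words.

During stance at least one plantar sensor is pressed, so the fused word is
well above zero; in the air all sensors read zero.  The one exception is a
hardware artifact: Sensor 8 sometimes reports "slightly pressed" (level 1,
i.e. word == 1) in late swing, just before heel strike.  The swing
indicator therefore uses an inclusive cutoff,

    F(k) = 1  if p(k) <= threshold   (swing)
    F(k) = 0  otherwise              (stance)

with threshold = 1, which accepts both the all-off word 0 and the Sensor-8
artifact word 1 as swing.  Each maximal run of F = 1 is one swing phase,
and the stride count is the number of swing phases.

A light debounce guards against chatter: swing runs shorter than
``min_swing_samples`` are flipped to stance, then interior stance runs
shorter than ``min_stance_samples`` are flipped to swing.  The defaults
(5 samples = 0.1 s at 50 Hz) are far below physiological swing/stance
durations, so real phases are never suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import InsoleRecording

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    threshold: int = 1
    min_swing_samples: int = 5
    min_stance_samples: int = 5

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.min_swing_samples < 1 or self.min_stance_samples < 1:
            raise ValueError("debounce lengths must be >= 1")


@dataclass(frozen=True)
class StrideSegment:
    """A maximal swing run as a half-open sample interval [start_idx, stop_idx)."""

    start_idx: int
    stop_idx: int
    start_time: float
    stop_time: float
    n_samples: int
    duration: float

    @classmethod
    def from_indices(cls, start: int, stop: int, fs: float) -> "StrideSegment":
        return cls(
            start_idx=start,
            stop_idx=stop,
            start_time=start / fs,
            stop_time=stop / fs,
            n_samples=stop - start,
            duration=(stop - start) / fs,
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a binary array as (start, stop, value)."""
    mask = np.asarray(mask)
    if len(mask) == 0:
        return []
    edges = np.flatnonzero(np.diff(mask)) + 1
    bounds = np.concatenate(([0], edges, [len(mask)]))
    return [
        (int(bounds[i]), int(bounds[i + 1]), int(mask[bounds[i]]))
        for i in range(len(bounds) - 1)
    ]


def debounce(mask: np.ndarray, min_swing: int, min_stance: int) -> np.ndarray:
    """Remove sub-physiological chatter from a raw swing mask.

    Short swing runs (wherever they occur) are flipped to stance; then
    stance runs strictly between two swing runs and shorter than
    ``min_stance`` are flipped to swing, merging their neighbours.  The
    result is a fixed point: re-applying the same debounce is a no-op.
    """
    m = np.asarray(mask).astype(np.uint8).copy()
    for start, stop, value in _runs(m):
        if value == 1 and stop - start < min_swing:
            m[start:stop] = 0
    runs = _runs(m)
    for i, (start, stop, value) in enumerate(runs):
        if value == 0 and 0 < i < len(runs) - 1 and stop - start < min_stance:
            m[start:stop] = 1
    return m


def swing_mask(
    recording: InsoleRecording, params: SegmentationParams | None = None
) -> np.ndarray:
    """Per-sample binary swing indicator F(k) (1 = swing), debounced."""
    params = params or SegmentationParams()
    raw = (recording.pressure <= params.threshold).astype(np.uint8)
    return debounce(raw, params.min_swing_samples, params.min_stance_samples)


def stride_segments(mask: np.ndarray, fs: float) -> list[StrideSegment]:
    """Extract maximal swing runs as stride segments, in temporal order.

    Runs touching either recording boundary are incomplete swings (the
    lift-off or landing was not captured); they are dropped with a warning
    rather than integrated.
    """
    mask = np.asarray(mask)
    segments: list[StrideSegment] = []
    for start, stop, value in _runs(mask):
        if value != 1:
            continue
        if start == 0 or stop == len(mask):
            logger.warning(
                "dropping incomplete swing run [%d, %d) touching the recording boundary",
                start,
                stop,
            )
            continue
        segments.append(StrideSegment.from_indices(start, stop, fs))
    return segments


def count_strides(segments: list[StrideSegment]) -> int:
    """Stride count: one stride per complete swing phase."""
    return len(segments)
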