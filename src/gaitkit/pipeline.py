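"""End-to-end processing pipeline and its configuration.

The stages run in fixed order: gravity separation -> band-pass ->
pressure-based swing mask -> stride segments -> per-stride double
integration -> cumulative distance.  The configuration bundles every
stage's parameters; the defaults are the method's operating constants
(fs = 50 Hz, alpha = 0.8, band-pass 5-10 Hz, pressure threshold 1,
L0 = 0.26 m).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .distance import (
    DistanceEstimate,
    DistanceParams,
    effective_ratios,
    estimate_distance,
    integrate_stride,
    mask_acceleration,
)
from .exceptions import ConfigError
from .io import InsoleRecording
from .preprocessing import FilterParams, bandpass, separate_gravity
from .segmentation import (
    SegmentationParams,
    StrideSegment,
    stride_segments,
    swing_mask,
)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one serialisable document."""

    fs: float = 50.0
    filter: FilterParams = field(default_factory=FilterParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    distance: DistanceParams = field(default_factory=DistanceParams)

    def to_dict(self) -> dict[str, Any]:
        return {
            "fs": self.fs,
            "filter": asdict(self.filter),
            "segmentation": asdict(self.segmentation),
            "distance": asdict(self.distance),
        }

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        try:
            return cls(
                fs=float(doc.get("fs", 50.0)),
                filter=FilterParams(**doc.get("filter", {})),
                segmentation=SegmentationParams(**doc.get("segmentation", {})),
                distance=DistanceParams(**doc.get("distance", {})),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline configuration: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML document."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return PipelineConfig.from_dict(doc)


@dataclass
class WalkMeasurement:
    """Intermediate per-recording quantities shared by estimation and calibration."""

    mask: np.ndarray
    segments: list[StrideSegment]
    ratios: list[float]  # effective per-stride dMAG/|dz| (median fallback applied)

    @property
    def n_strides(self) -> int:
        return len(self.segments)

    @property
    def sum_ratio(self) -> float:
        return float(sum(self.ratios))


def preprocess(recording: InsoleRecording, config: PipelineConfig) -> np.ndarray:
    """Gravity separation followed by the (optional) band-pass stage."""
    linear = separate_gravity(recording, config.filter)
    return bandpass(linear, config.filter, recording.fs)


def measure_walk(recording: InsoleRecording, config: PipelineConfig) -> WalkMeasurement:
    """Run the pipeline up to (and including) per-stride ratios.

    Calibration needs the per-stride ratios but not a K; this helper keeps
    the measurement identical between estimation and calibration.
    """
    series = preprocess(recording, config)
    mask = swing_mask(recording, config.segmentation)
    masked = mask_acceleration(series, mask)
    segments = stride_segments(mask, recording.fs)
    integrals = [
        integrate_stride(masked, seg, recording.fs, dz_epsilon=config.distance.dz_epsilon)
        for seg in segments
    ]
    ratios = effective_ratios(integrals) if integrals else []
    return WalkMeasurement(mask=mask, segments=segments, ratios=ratios)


def run_pipeline(recording: InsoleRecording, config: PipelineConfig) -> DistanceEstimate:
    """Full pipeline: recording in, cumulative distance estimate out."""
    series = preprocess(recording, config)
    mask = swing_mask(recording, config.segmentation)
    masked = mask_acceleration(series, mask)
    segments = stride_segments(mask, recording.fs)
    return estimate_distance(masked, segments, config.distance, recording.fs)
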