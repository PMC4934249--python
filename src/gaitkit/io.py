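"""Recording container and on-disk format.

A recording is a uniformly sampled sequence of (timestamp, raw triaxial
acceleration, fused pressure word) rows.  On disk it is a plain CSV with
header ``t,ax,ay,az,pressure`` (comma-separated, '.' decimal, UTF-8) and an
optional JSON sidecar ``<name>.meta.json`` carrying the sampling rate,
subject label and reference distance:

    {"fs": 50.0, "subject": "s01", "reference_distance_m": 16.0}

Acceleration is stored in m/s^2 so that double integration yields metres
with no hidden conversion.  Timestamps are explicit (not implied by row
index) so dropped samples are detectable; uniform spacing is enforced, not
repaired — resampling is out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .codec import MAX_WORD
from .exceptions import RecordingParseError

DEFAULT_FS = 50.0
_COLUMNS = ["t", "ax", "ay", "az", "pressure"]
#: relative tolerance on the sample spacing 1/fs
_DT_RTOL = 1e-6


@dataclass
class RecordingMeta:
    """Free-form recording metadata."""

    subject: str | None = None
    reference_distance_m: float | None = None
    annotations: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class SensorSample:
    """A single row of a recording (convenience view, not the storage format)."""

    t: float
    axr: float
    ayr: float
    azr: float
    pressure: int


@dataclass
class InsoleRecording:
    """A time-synchronized insole recording.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Seconds since recording start, strictly increasing, uniformly
        spaced at 1/fs.
    accel : ndarray, shape (n, 3)
        Raw acceleration (gravity included) on X, Y, Z in m/s^2.
    pressure : ndarray, shape (n,)
        Fused 16-bit pressure words.
    fs : float
        Sampling frequency in Hz (hardware default 50).
    meta : RecordingMeta
        Subject label, optional reference distance, annotations.
    """

    t: np.ndarray
    accel: np.ndarray
    pressure: np.ndarray
    fs: float = DEFAULT_FS
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.pressure = np.asarray(self.pressure)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("recording needs at least 2 samples")
        n = len(self.t)
        if self.accel.shape != (n, 3):
            raise ValueError(f"accel must have shape ({n}, 3), got {self.accel.shape}")
        if self.pressure.shape != (n,):
            raise ValueError(f"pressure must have shape ({n},), got {self.pressure.shape}")
        if not np.issubdtype(self.pressure.dtype, np.integer):
            as_int = self.pressure.astype(np.int64)
            if not np.array_equal(as_int, self.pressure):
                raise ValueError("pressure words must be integers")
            self.pressure = as_int
        if self.pressure.min(initial=0) < 0 or self.pressure.max(initial=0) > MAX_WORD:
            bad = int(np.argmax((self.pressure < 0) | (self.pressure > MAX_WORD)))
            raise ValueError(
                f"pressure word {self.pressure[bad]} at sample {bad} outside [0, {MAX_WORD}]"
            )
        if not (self.fs > 0) or not math.isfinite(self.fs):
            raise ValueError(f"fs must be positive and finite, got {self.fs}")
        if self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise ValueError(f"timestamps not strictly increasing at sample {bad + 1}")
        target = 1.0 / self.fs
        off = np.abs(dt - target) > _DT_RTOL * target
        if np.any(off):
            bad = int(np.argmax(off))
            raise ValueError(
                f"non-uniform sample spacing at sample {bad + 1}: "
                f"dt={dt[bad]:.9g}, expected {target:.9g} (fs={self.fs})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.t[-1] - self.t[0])

    def sample(self, i: int) -> SensorSample:
        return SensorSample(
            t=float(self.t[i]),
            axr=float(self.accel[i, 0]),
            ayr=float(self.accel[i, 1]),
            azr=float(self.accel[i, 2]),
            pressure=int(self.pressure[i]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "ax": self.accel[:, 0],
                "ay": self.accel[:, 1],
                "az": self.accel[:, 2],
                "pressure": self.pressure,
            }
        )


def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".meta.json")


def write_recording(recording: InsoleRecording, path: str | Path) -> None:
    """Write a recording as CSV plus JSON metadata sidecar.

    Floats are written with 17 significant digits so that a write/read
    round trip reproduces them bit-exactly.
    """
    path = Path(path)
    recording.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "fs": recording.fs,
        "subject": recording.meta.subject,
        "reference_distance_m": recording.meta.reference_distance_m,
    }
    if recording.meta.annotations:
        sidecar["annotations"] = recording.meta.annotations
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path) -> InsoleRecording:
    """Read a recording CSV (and its sidecar, if present).

    A missing sidecar defaults the sampling rate to 50 Hz.  Malformed rows,
    out-of-range pressure words and non-monotone or non-uniform timestamps
    raise :class:`RecordingParseError` naming the offending line (header is
    line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise RecordingParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if list(df.columns) != _COLUMNS:
        raise RecordingParseError(
            f"{path}: expected header {','.join(_COLUMNS)!r}, got {','.join(map(str, df.columns))!r}"
        )
    for col in _COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric)
        if bad.any():
            line = int(np.argmax(bad.to_numpy())) + 2
            raise RecordingParseError(f"{path}: line {line}: malformed value in column {col!r}")
        df[col] = numeric
    pressure = df["pressure"].to_numpy()
    if np.any(pressure != np.round(pressure)):
        line = int(np.argmax(pressure != np.round(pressure))) + 2
        raise RecordingParseError(f"{path}: line {line}: pressure word is not an integer")
    pressure = pressure.astype(np.int64)
    out_of_range = (pressure < 0) | (pressure > MAX_WORD)
    if np.any(out_of_range):
        line = int(np.argmax(out_of_range)) + 2
        raise RecordingParseError(
            f"{path}: line {line}: pressure word {pressure[line - 2]} outside [0, {MAX_WORD}]"
        )

    fs = DEFAULT_FS
    meta = RecordingMeta()
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            doc = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise RecordingParseError(f"{sidecar}: invalid JSON: {exc}") from exc
        fs = float(doc.get("fs", DEFAULT_FS))
        meta = RecordingMeta(
            subject=doc.get("subject"),
            reference_distance_m=doc.get("reference_distance_m"),
            annotations=doc.get("annotations", {}),
        )
    try:
        return InsoleRecording(
            t=df["t"].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            pressure=pressure,
            fs=fs,
            meta=meta,
        )
    except ValueError as exc:
        raise RecordingParseError(f"{path}: {exc}") from exc
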