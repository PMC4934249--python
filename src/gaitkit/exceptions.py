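"""Exception hierarchy.

Every error raised by the library derives from :class:`GaitKitError`; the
``exit_code`` attribute gives the process exit status the CLI maps it to
(code 3 is reserved for plain I/O failures such as a missing file).
"""


class GaitKitError(Exception):
    """Base class for all gaitkit errors."""

    exit_code = 1


class RecordingParseError(GaitKitError):
    """A recording file is malformed (bad row, out-of-range value, non-monotone time)."""

    exit_code = 4


class ConfigError(GaitKitError):
    """Invalid pipeline configuration (e.g. band-pass corner above Nyquist)."""

    exit_code = 5


class NoStridesError(GaitKitError):
    """No complete swing phase was found in the recording."""

    exit_code = 6


class DegenerateVerticalError(GaitKitError):
    """Every stride has vertical displacement below the epsilon guard."""

    exit_code = 7


class CalibrationError(GaitKitError):
    """Calibration produced a non-positive or undefined coefficient."""

    exit_code = 8
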