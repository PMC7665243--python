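"""Exception hierarchy.

Every error raised by the package derives from :class:`LineBPError` so callers
(and the CLI) can map failures onto machine-readable categories.
"""

from __future__ import annotations


class LineBPError(Exception):
    """Base class for all package errors."""

    #: short machine-readable category, used by the CLI for structured errors
    category = "error"


class InvalidParameterError(LineBPError, ValueError):
    """A parameter is outside its valid domain (e.g. zero flow, width < 1)."""

    category = "invalid-parameter"


class OutOfRangeError(LineBPError, ValueError):
    """A query time falls outside the span of a trace."""

    category = "out-of-range"


class NoPumpSignalError(LineBPError):
    """No in-band spectral peak exceeds the detection threshold.

    Signals that the blood pump is off (or a sensor fault) for the window in
    question; pipelines treat it as a gap, not a failure.
    """

    category = "no-pump-signal"


class NoCalibrationError(LineBPError):
    """A session has no usable cuff/line measurement pair, so C is undefined."""

    category = "no-calibration"


class NoEstimateError(LineBPError):
    """Continuous estimation requested but no flow estimates are available."""

    category = "no-estimate"


class DegenerateFitError(LineBPError):
    """Regression input has too few points or zero predictor variance."""

    category = "degenerate-fit"


class FormatError(LineBPError):
    """A file does not conform to the documented on-disk schema."""

    category = "format-error"
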