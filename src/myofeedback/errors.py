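"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`MyofeedbackError`, so callers (and the CLI) can catch one type.
"""


class MyofeedbackError(Exception):
    """Base class for all errors raised by myofeedback."""


class InvalidScriptError(MyofeedbackError):
    """An activation script is malformed (overlapping or out-of-range segments)."""


class RateMismatchError(MyofeedbackError):
    """Sampling rates of two objects that must agree do not."""


class UnitsError(MyofeedbackError):
    """A recording is in the wrong units for the requested operation."""


class BandError(MyofeedbackError):
    """A filter band is invalid for the sampling rate."""


class WindowError(MyofeedbackError):
    """A smoothing window is invalid (non-positive or longer than the data)."""


class CalibrationError(MyofeedbackError):
    """Grip calibration failed, e.g. a silent channel."""


class UnknownChannelError(MyofeedbackError):
    """A channel label is not present in a recording or profile."""


class ScoreTableError(MyofeedbackError):
    """A score table violates its schema (bad bins or probabilities)."""


class ProtocolError(MyofeedbackError):
    """A session protocol is inconsistent with the supplied data."""


class DegenerateDataError(MyofeedbackError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class FormatError(MyofeedbackError):
    """An on-disk artifact failed to parse or validate.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
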