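"""Exception types shared across the package."""


class IodoperfError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(IodoperfError, ValueError):
    """Raised when phantom kinetics cannot be calibrated to the requested targets."""


class FitInputError(IodoperfError, ValueError):
    """Raised for invalid inputs to the curve-fitting routines."""


class UndefinedMetricError(IodoperfError, ZeroDivisionError):
    """Raised when a contrast metric is undefined (e.g. zero reference signal)."""


class FormatError(IodoperfError, ValueError):
    """Raised when an on-disk series or sidecar fails validation."""
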