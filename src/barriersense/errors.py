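"""Exception hierarchy shared across the package."""

from __future__ import annotations


class BarrierSenseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BarrierSenseError, ValueError):
    """An argument violates an operation's precondition."""


class NonConvergenceError(BarrierSenseError, RuntimeError):
    """Curve fitting failed after all restarts.

    Attributes
    ----------
    residual_norm : float or None
        Residual norm of the last attempted fit, if any attempt ran.
    """

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class OutOfRangeError(BarrierSenseError, ValueError):
    """An intensity lies outside the invertible range of a calibration curve.

    Attributes
    ----------
    asymptote : str
        Which asymptote bound was violated: ``"lower"`` or ``"upper"``.
    """

    def __init__(self, message: str, asymptote: str):
        super().__init__(message)
        self.asymptote = asymptote


class DegeneratePixelError(InvalidInputError):
    """A pixel with non-positive mean intensity blocks mask estimation.

    Attributes
    ----------
    pixels : list of (row, col)
        Coordinates of the offending pixels.
    """

    def __init__(self, message: str, pixels):
        super().__init__(message)
        self.pixels = list(pixels)


class UndefinedRatioError(InvalidInputError):
    """A ratio with a zero or negative denominator was requested."""


class InvalidMeasurementError(InvalidInputError):
    """A measured value implies a physically impossible parameter."""


class ConfigurationError(BarrierSenseError):
    """A run configuration is incomplete or inconsistent."""


class SchemaError(ConfigurationError):
    """A config field is missing, malformed, or carries the wrong unit.

    Attributes
    ----------
    field : str
        Dotted path of the offending field.
    expected : str
        Human-readable description of what was expected.
    """

    def __init__(self, field: str, expected: str):
        super().__init__(f"config field '{field}': expected {expected}")
        self.field = field
        self.expected = expected
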