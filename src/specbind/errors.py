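"""Exception and warning types shared across the package."""


class SpecbindError(Exception):
    """Base class for all package errors."""


class ParseError(SpecbindError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(SpecbindError, ValueError):
    """An input violates a documented invariant."""


class RangeError(SpecbindError, ValueError):
    """A wavelength or grid point falls outside the spectral span."""


class InsufficientDataError(SpecbindError):
    """Too few usable points for the requested fit."""


class FitError(SpecbindError):
    """A nonlinear fit failed to converge or produced a degenerate estimate."""


class ExtrapolationWarning(UserWarning):
    """The response never crosses its half-maximum inside the measured span."""


class DataQualityWarning(UserWarning):
    """A data point was excluded or flagged during analysis."""
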