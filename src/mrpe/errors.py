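"""Exception and warning types shared across the package."""


class MRPEError(Exception):
    """Base class for all package errors."""


class ParameterError(MRPEError, ValueError):
    """An argument is outside its documented domain (m < 2, alpha <= 0, ...)."""


class InvalidInputError(MRPEError, ValueError):
    """Input data violates a contract (non-finite values, bad group count, ...)."""


class LengthError(MRPEError, ValueError):
    """The series is too short for the requested (m, tau, s)."""

    def __init__(self, message: str, *, required: int, actual: int):
        super().__init__(message)
        self.required = required
        self.actual = actual


class DegenerateSeriesError(MRPEError, ValueError):
    """All embedding windows carry zero weight (e.g. a constant series)."""


class ParseError(MRPEError, ValueError):
    """An RR file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, *, line: int):
        super().__init__(message)
        self.line = line


class SeriesLengthWarning(UserWarning):
    """The series does not satisfy the recommended T > 5*m! sample-size rule."""
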