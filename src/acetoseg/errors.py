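"""Exception hierarchy for acetoseg."""


class AcetosegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AcetosegError):
    """Input violates a documented precondition (wrong shape, count, range)."""


class DegeneracyError(AcetosegError):
    """Point geometry is degenerate (collinear/duplicate correspondences,
    rank-deficient design matrix, or a point on the vanishing line)."""


class ParseError(AcetosegError):
    """A text file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
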