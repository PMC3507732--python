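"""Exception hierarchy.

Validation problems (bad inputs, malformed files) and fit failures are kept
distinct so the CLI can map them to different exit codes (2 and 3).
"""


class BarofoldError(Exception):
    """Base class for all package errors."""


class ValidationError(BarofoldError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A data file could not be parsed; message carries the line number."""


class UndefinedObservableError(ValidationError):
    """The requested observable is undefined (e.g. csm of a dark spectrum)."""


class ExtrapolationError(ValidationError):
    """A query point lies outside the sampled grid."""


class InsufficientDataError(ValidationError):
    """Too few points to determine the requested quantity."""


class FitFailureError(BarofoldError):
    """Nonlinear least squares failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateFitError(FitFailureError):
    """The data carry no information about the parameter (e.g. zero amplitude)."""
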