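"""Exception hierarchy for the gagfib pipeline.

Every error raised by the package derives from :class:`GagfibError`, so callers
(and the CLI) can catch pipeline failures without swallowing programming errors.
"""


class GagfibError(Exception):
    """Base class for all gagfib errors."""


class SchemaError(GagfibError):
    """A required column is missing or the column map is inconsistent."""


class ParseError(GagfibError):
    """A cell could not be parsed; carries row and column context."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class EmptyInputError(GagfibError):
    """The input file or entry list contains no data rows."""


class EntryValidationError(GagfibError):
    """A dataset entry violates one of the schema invariants."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DegenerateEncodingError(GagfibError):
    """A categorical variable has fewer than two observed levels."""


class InsufficientDataError(GagfibError):
    """Too few observations (or a constant predictor) for the requested analysis."""


class DegenerateTraceError(GagfibError):
    """A kinetic trace carries no usable signal (e.g. constant intensity)."""


class FitFailureError(GagfibError):
    """Nonlinear least squares failed to converge after all restarts."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DomainError(GagfibError):
    """An argument lies outside the mathematical domain of the operation."""


class SingularDesignError(GagfibError):
    """The design matrix is rank deficient."""


class NoModelError(GagfibError):
    """No candidate model satisfies the acceptance criteria; lists near misses."""

    def __init__(self, message: str, near_misses: list | None = None):
        super().__init__(message)
        self.near_misses = near_misses or []
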