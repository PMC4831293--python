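"""Exception hierarchy for catalog parsing, validation, and estimation."""


class ParityMetaError(Exception):
    """Base class for all package errors."""


class ParseError(ParityMetaError):
    """A catalog file violates the documented CSV schema."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))
        self.row = row
        self.column = column


class ValidationError(ParityMetaError):
    """A study report violates a structural invariant."""

    def __init__(self, message: str, report_id: str | None = None):
        super().__init__(f"{report_id}: {message}" if report_id else message)
        self.report_id = report_id


class DomainError(ParityMetaError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateIntervalError(DomainError):
    """A confidence interval has zero width and carries no standard error."""


class NoDataError(ParityMetaError):
    """An operation received an empty selection."""


class InsufficientDataError(ParityMetaError):
    """Fewer inputs than the estimator requires."""


class SingularDesignError(ParityMetaError):
    """The regression design matrix is not of full rank."""


class ConvergenceError(ParityMetaError):
    """An iterative pseudo-count fit failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
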