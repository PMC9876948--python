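"""Exception types shared across the package."""


class AppendiscoreError(Exception):
    """Base class for package errors."""


class MissingDataError(AppendiscoreError):
    """A required clinical field is absent; scores are never imputed."""

    def __init__(self, field: str, record: int | None = None):
        self.field = field
        self.record = record
        where = f" (record {record})" if record is not None else ""
        super().__init__(f"missing required field '{field}'{where}")


class CohortValidationError(AppendiscoreError):
    """One or more cohort records failed validation.

    Carries every (row, message) pair rather than stopping at the first
    failure, so a malformed CSV can be fixed in one pass.
    """

    def __init__(self, failures: list[tuple[int, str]]):
        self.failures = list(failures)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.failures[:10])
        extra = "" if len(self.failures) <= 10 else f" (+{len(self.failures) - 10} more)"
        super().__init__(f"{len(self.failures)} invalid record(s): {lines}{extra}")


class ImpossibleRowError(AppendiscoreError):
    """No integer confusion matrix on the given marginals reproduces the
    reported sensitivity/specificity at their printed precision."""


class DegenerateInputError(AppendiscoreError):
    """Input lacks the variation an operation requires (e.g. single-class
    labels for a ROC curve, zero variance for a correlation)."""
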