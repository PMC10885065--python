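"""Exception hierarchy shared across the toolkit."""


class StepTestError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(StepTestError):
    """An input violates a documented precondition or invariant."""


class InsufficientDataError(StepTestError):
    """A phase or averaging window does not contain enough samples."""


class DegenerateFitError(StepTestError):
    """The HR-VO2 regression cannot be identified (e.g. zero HR variance)."""


class DegenerateDesignError(StepTestError):
    """The regression design matrix is rank deficient (collinear columns)."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class ModelError(StepTestError):
    """A prediction model is malformed or queried with unknown predictors."""


class UndefinedStatisticError(StepTestError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ConfigurationError(StepTestError):
    """A simulation or run configuration is internally inconsistent."""
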