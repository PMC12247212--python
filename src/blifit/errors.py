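"""Exception hierarchy.

Every error raised by blifit derives from :class:`BlifitError`, so callers
(notably the CLI) can map failures onto machine-readable error classes.
"""


class BlifitError(Exception):
    """Base class for all blifit errors."""

    #: short machine-readable class used in CLI reports
    error_class = "internal"


class FormatError(BlifitError):
    """A file is structurally wrong (missing column, bad header, bad key)."""

    error_class = "format"


class ParseError(BlifitError):
    """A cell or field could not be parsed; carries the offending row."""

    error_class = "parse"

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(BlifitError):
    """Data violates a model invariant (non-increasing time, bad schedule...)."""

    error_class = "validation"


class CoverageError(BlifitError):
    """A sensorgram does not cover the scheduled assay duration."""

    error_class = "coverage"


class AlignmentError(BlifitError):
    """Two traces cannot be brought onto a common time grid."""

    error_class = "alignment"


class DomainError(BlifitError, ValueError):
    """An argument is outside the mathematical domain of an operation."""

    error_class = "domain"


class ModelError(BlifitError):
    """A model cannot be evaluated for the given schedule/parameters."""

    error_class = "model"


class GuessError(BlifitError):
    """No sensible starting point could be derived from the data."""

    error_class = "guess"


class ConvergenceError(BlifitError):
    """The optimizer failed to converge; carries best-so-far diagnostics."""

    error_class = "convergence"

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class DofError(BlifitError):
    """Fewer data points than free parameters (or no residual dof)."""

    error_class = "dof"


class DataError(BlifitError):
    """Not enough (or unusable) data for the requested analysis."""

    error_class = "data"


class UncertaintyError(BlifitError):
    """Standard errors are unavailable (singular/ill-conditioned Jacobian)."""

    error_class = "uncertainty"

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class ConfigError(BlifitError):
    """A run configuration is invalid or references missing files."""

    error_class = "config"
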