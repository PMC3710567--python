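"""Exception hierarchy shared across the package."""


class LtssError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LtssError):
    """A required column is missing or a column mapping is invalid."""


class InputError(LtssError):
    """The input file is empty or unreadable."""


class IntegrityError(LtssError):
    """Duplicate (state, year) keys or other uniqueness violations."""


class ConfigurationError(LtssError):
    """An option, rule, or specification is internally inconsistent."""


class CoverageError(LtssError):
    """A lookup series (e.g. CPI) does not cover a required year."""


class DomainError(LtssError):
    """A value is outside the mathematical domain of an operation."""


class JoinError(LtssError):
    """Two tables that must align on (state, year) share no keys."""


class SingularityError(LtssError):
    """A design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConvergenceError(LtssError):
    """An iterative fit failed to converge."""
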