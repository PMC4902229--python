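"""Exception types shared across the package."""


class NephromorphError(Exception):
    """Base class for package errors."""


class InvalidParameterError(NephromorphError, ValueError):
    """A generator or estimator parameter violates its constraints."""


class InsufficientGlomeruliError(NephromorphError):
    """Fewer than the minimum number of glomeruli needed for tuft-area
    estimation (such cases are excluded from morphometry)."""


class UndefinedResultError(NephromorphError):
    """A requested statistic is undefined for the given input (zero
    points, constant column, zero reference SSR, ...)."""


class SingularDesignError(NephromorphError):
    """The regression design matrix is rank-deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])


class ConvergenceError(NephromorphError):
    """Iterative fitting failed to converge."""


class SchemaError(NephromorphError, KeyError):
    """A required column is missing or unparseable in an input table."""


class StratificationError(NephromorphError):
    """Quantile stratification produced an empty stratum."""
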