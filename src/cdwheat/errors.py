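"""Exception hierarchy shared across the package."""


class CdwheatError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CdwheatError):
    """A required column is missing or a cell cannot be parsed."""


class ValidationError(CdwheatError):
    """A record violates a physical or bookkeeping invariant."""


class MissingColumnError(CdwheatError):
    """An operation needs a column that the dataset does not carry."""


class UndefinedRatioError(CdwheatError):
    """BCF requested with zero soil concentration in the denominator."""


class InsufficientDataError(CdwheatError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(CdwheatError):
    """Pearson correlation requested against a zero-variance variable."""


class DegenerateThresholdError(CdwheatError):
    """No admissible threshold candidate (threshold variable too coarse)."""


class RegimeSingularityError(CdwheatError):
    """The regression design is singular within one regime."""


class DegenerateVarianceError(CdwheatError):
    """Residual variance is zero, so LR statistics are undefined."""


class ConfigurationError(CdwheatError):
    """An invalid generator, bootstrap, or pipeline configuration."""
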