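"""Exception hierarchy shared across the pipeline."""


class OpenArmsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OpenArmsError):
    """A data file could not be parsed."""


class ValidationError(OpenArmsError):
    """An input violates a structural invariant (e.g. non-monotone time)."""


class DataQualityError(OpenArmsError):
    """Data are structurally valid but unusable (e.g. a tracking gap > 1 s)."""


class ConfigError(OpenArmsError):
    """A configuration value is inconsistent or infeasible."""


class CollinearityError(OpenArmsError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message, predictors=()):
        super().__init__(message)
        self.predictors = tuple(predictors)


class DegenerateDataError(OpenArmsError):
    """Statistic undefined on this input (e.g. zero variance)."""


class EmptyResultError(OpenArmsError):
    """An operation produced no usable output (e.g. all events dropped)."""
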