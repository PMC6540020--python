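"""Exception hierarchy shared across the pipeline."""


class WristBiaError(Exception):
    """Base class for all package errors."""


class MalformedSeriesError(WristBiaError):
    """An impedance series violates its structural invariants."""


class DegenerateDeltaError(WristBiaError):
    """A delta-ratio denominator is zero; the caller must take the fallback path."""


class InsufficientSamplesError(WristBiaError):
    """Too few usable deltas to fit the log-linear decay model."""


class SchemaError(WristBiaError):
    """A feature vector or record is missing a field or has mismatched shape."""


class SingularDesignError(WristBiaError):
    """The regression design matrix is rank deficient."""


class DivergenceError(WristBiaError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class UndefinedCorrelationError(WristBiaError):
    """Correlation requested on a zero-variance vector."""


class SplitError(WristBiaError):
    """Train/test split cannot be satisfied by the cohort."""


class ConfigError(WristBiaError):
    """Invalid configuration value."""


class ParseError(WristBiaError):
    """A CSV/JSON input could not be parsed; message names the offending line."""
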