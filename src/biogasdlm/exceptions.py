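"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`BiogasDLMError`, so callers can catch the whole family at once.
"""


class BiogasDLMError(Exception):
    """Base class for all errors raised by biogasdlm."""


class SchemaError(BiogasDLMError):
    """A required column / regressor is missing or unknown."""


class GapError(BiogasDLMError):
    """Timestamps are not a uniform, strictly increasing hourly grid."""


class ValidationError(BiogasDLMError):
    """Values violate a data invariant (negative, missing, duplicated)."""


class BoundsError(BiogasDLMError):
    """A window or lag request exceeds the available history/future."""


class DegenerateInputError(BiogasDLMError):
    """An input has no usable variation (e.g. zero variance)."""


class SingularDesignError(BiogasDLMError):
    """The lagged design matrix is numerically rank deficient.

    Carries the names of the offending columns; rank deficiency is a hard
    error here — coefficients of a collinear design are meaningless for
    kinetics interpretation, so columns are never silently dropped.
    """

    def __init__(self, message: str, columns: tuple = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class UndefinedMetricError(BiogasDLMError):
    """A metric is undefined for the given inputs (e.g. MAPE on all zeros)."""


class EvaluationError(BiogasDLMError):
    """A rolling evaluation produced no valid forecast origin."""


class ConfigMismatchError(BiogasDLMError):
    """Runs with heterogeneous model settings cannot be aggregated."""


class ParameterError(BiogasDLMError):
    """A scenario / kernel parameter set is infeasible."""
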