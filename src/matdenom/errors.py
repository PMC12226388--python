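"""Exception hierarchy for the pipeline."""


class MatdenomError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MatdenomError):
    """Schema or run configuration is unusable (e.g. a missing mandatory column)."""


class SurveyValidationError(MatdenomError):
    """Survey data violate a structural invariant (e.g. orphan records)."""


class DegenerateInputError(MatdenomError):
    """An estimator input makes the statistic undefined (e.g. zero exposure with deaths)."""


class EmptyDistributionError(MatdenomError):
    """No pregnancy records fall inside any respondent's calendar window."""


class UndefinedFactorError(MatdenomError):
    """An adjustment factor is undefined (zero live births with non-live outcomes)."""


class CapabilityError(MatdenomError):
    """The survey lacks a field the requested metric needs (e.g. violence flags for MMR)."""


class ReplicateFailureError(MatdenomError):
    """The statistic failed on one or more delete-one-cluster subsamples."""


class ParameterError(MatdenomError):
    """Simulation parameters are invalid or infeasible."""
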