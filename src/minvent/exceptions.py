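"""Exception hierarchy shared across the toolkit."""


class MinventError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MinventError):
    """A column map, unit declaration, or config file is invalid."""


class InputError(MinventError):
    """An input file or value violates a hard precondition."""


class DomainError(MinventError, ValueError):
    """A numeric argument is outside the mathematical domain (e.g. HR <= 0)."""


class MissingPredictorError(MinventError):
    """A model requires a predictor that was not supplied."""


class UnavailableFVCError(MinventError):
    """Neither a measured nor a predicted FVC is available under the chosen policy."""


class UnavailablePredictionError(MinventError):
    """A reference-equation prediction cannot be made (missing height/age or table row)."""


class NotConvergedError(MinventError):
    """The mixed-model optimizer failed to converge."""
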