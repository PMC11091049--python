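"""Exception hierarchy used across the package."""


class InsepError(Exception):
    """Base class for package errors."""


class SchemaError(InsepError, ValueError):
    """A required column or field is missing from an input table."""


class ValidationError(InsepError, ValueError):
    """Input data violate a structural invariant (grids, signs, lengths)."""


class DomainError(InsepError, ValueError):
    """A numeric argument lies outside its physical domain."""


class EstimationError(InsepError, RuntimeError):
    """A model fit cannot be carried out on the given data."""


class NonIdentifiabilityWarning(UserWarning):
    """Fitted parameters are jointly unidentifiable (e.g. only their product
    is constrained by the data)."""


class ConvergenceWarning(UserWarning):
    """An optimizer stopped without meeting its convergence tolerances."""
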