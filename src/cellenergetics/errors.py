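"""Exception and warning types shared across the package."""


class CellEnergeticsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CellEnergeticsError, ValueError):
    """An argument violates a precondition (non-positive volume, negative area, ...)."""


class DomainValidityError(CellEnergeticsError, ValueError):
    """Inputs are formally acceptable but outside the model's domain of validity."""


class InsufficientDataError(CellEnergeticsError, ValueError):
    """Too few observations to perform the requested estimation."""


class SchemaError(CellEnergeticsError, ValueError):
    """A tabular input is missing mandatory columns or violates table invariants."""


class ConfigurationError(CellEnergeticsError, ValueError):
    """A configuration object or file is internally inconsistent."""


class PipelineError(CellEnergeticsError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the offending input."""


class ExtrapolationWarning(UserWarning):
    """Model applied outside the parameter range it was calibrated for."""
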