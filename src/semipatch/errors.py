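"""Exception hierarchy shared across the pipeline stages."""


class SemipatchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SemipatchError):
    """Invalid or inconsistent configuration values."""


class DataError(SemipatchError):
    """Input data violates a precondition (too few items, missing class, ...)."""


class FormatError(SemipatchError):
    """On-disk data does not conform to the expected layout."""


class DimensionError(SemipatchError):
    """A requested dimensionality is incompatible with the data."""


class ArchitectureError(SemipatchError):
    """Network topology inconsistent with the input size."""


class DivergenceError(SemipatchError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class GenerationError(SemipatchError):
    """Synthetic data could not be generated under the constraints."""


class DegenerateError(SemipatchError):
    """A statistic is undefined for the given input (zero variance, equal values)."""


class UndefinedMeasureError(SemipatchError):
    """A concept measure is undefined for a patch (empty mask, constant image)."""
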