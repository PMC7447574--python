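"""Exception hierarchy shared across the package."""


class DeepSubtypeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DeepSubtypeError, ValueError):
    """Invalid parameter or configuration value."""


class FormatError(DeepSubtypeError, ValueError):
    """Malformed input file (duplicate IDs, ragged rows, bad columns)."""


class DegenerateInputError(DeepSubtypeError, ValueError):
    """Input is structurally valid but degenerate for the operation."""


class AlignmentError(DeepSubtypeError, ValueError):
    """Sample or feature sets cannot be aligned."""


class DimensionError(DeepSubtypeError, ValueError):
    """Shape or feature-space mismatch."""


class TrainingDivergenceError(DeepSubtypeError, RuntimeError):
    """Non-finite loss encountered during autoencoder training."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class UndefinedMetricError(DeepSubtypeError, ValueError):
    """A clustering or survival metric is undefined for this input."""
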