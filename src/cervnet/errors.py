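"""Exception hierarchy shared across the package."""


class CervnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidShapeError(CervnetError):
    """An array does not have the shape an operation requires."""


class InvalidGroupsError(CervnetError):
    """Channel count is not divisible by the requested group count."""


class ConfigurationError(CervnetError):
    """A configuration object violates its invariants."""


class EmptyDatasetError(CervnetError):
    """A dataset directory or record list contains no usable images."""


class StratificationError(CervnetError):
    """A class has too few records to be split into train and validation."""


class DivergenceError(CervnetError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, step: int):
        self.epoch = epoch
        self.step = step
        super().__init__(f"training loss became non-finite at epoch {epoch}, step {step}")


class UnsupportedLayerError(CervnetError):
    """The complexity walker met a parameterised layer it cannot account for."""
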