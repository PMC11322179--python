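"""Exception hierarchy shared across the package."""


class EegcsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EegcsError, ValueError):
    """An invalid configuration value (band edges, layer specs, run configs)."""


class DimensionMismatchError(EegcsError, ValueError):
    """Array shapes that are mutually inconsistent (frame vs matrix, etc.)."""


class DegenerateFrameError(EegcsError, ValueError):
    """A frame whose population standard deviation is (numerically) zero."""


class TrainingDivergedError(EegcsError, RuntimeError):
    """Training produced a non-finite loss; carries the diagnostic state."""

    def __init__(self, message: str, epoch: int | None = None, batch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
        self.batch = batch
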