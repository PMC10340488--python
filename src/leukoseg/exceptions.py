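"""Exception hierarchy shared across the package."""


class LeukosegError(Exception):
    """Base class for all package errors."""


class DimensionError(LeukosegError, ValueError):
    """Raised when rasters that must share a shape do not."""


class DegenerateChannelError(LeukosegError, ValueError):
    """Raised when a color channel has zero mean and its constancy weight is undefined."""


class ConfigError(LeukosegError, ValueError):
    """Raised for out-of-range or inconsistent configuration values."""


class DegenerateCovarianceError(LeukosegError, ValueError):
    """Raised when a point cloud has no variance to project."""


class InsufficientDataError(LeukosegError, ValueError):
    """Raised when a class has too few samples for the requested statistic."""


class ZeroSpreadError(LeukosegError, ZeroDivisionError):
    """Raised when a Dist/SD ratio is requested for clusters with zero spread."""


class ModelError(LeukosegError, RuntimeError):
    """Raised when a model cannot be applied to the given input."""


class StageError(LeukosegError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
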