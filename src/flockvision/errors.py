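"""Exception hierarchy shared across the pipeline."""


class FlockVisionError(Exception):
    """Base class for all package errors."""


class FrameSourceError(FlockVisionError):
    """A frame source (video file or image directory) could not be read."""


class EmptySequenceError(FlockVisionError):
    """A frame source yielded zero decodable frames."""


class DimensionMismatchError(FlockVisionError):
    """Frames or masks that must share dimensions do not."""


class ParameterError(FlockVisionError):
    """A parameter is outside its valid range."""


class DegenerateHistogramError(FlockVisionError):
    """Otsu thresholding was attempted on a constant image.

    Typically means the frame equals the background everywhere; use a fixed
    threshold, or flag the frame as empty, instead of auto-thresholding.
    """


class EmptyForegroundError(FlockVisionError):
    """An operation requiring foreground pixels received an empty mask."""


class InvalidFrameError(FlockVisionError):
    """A frame cannot support the requested index (e.g. fewer than 2 blobs)."""


class DesignError(FlockVisionError):
    """The experimental design is incomplete or inconsistent."""


class ConfigurationError(FlockVisionError):
    """A synthetic-scene configuration is infeasible."""
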