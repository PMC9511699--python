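"""Exception hierarchy shared across the package."""


class FrameIndepError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(FrameIndepError):
    """Frames within one sequence do not share a single height/width."""


class BitDepthError(FrameIndepError):
    """Input frames are not 8-bit grayscale and rescaling was not requested."""


class BoundsError(FrameIndepError):
    """An ROI extends outside the frame it is placed on."""


class InvariantError(FrameIndepError):
    """A structural invariant is violated (e.g. inconsistent ROI counts)."""


class SchemaError(FrameIndepError):
    """A table is missing required columns/fields."""


class EmptyInputError(FrameIndepError):
    """An operation received an empty (or too small) pixel collection."""


class RangeError(FrameIndepError):
    """A parameter is outside its admissible range."""


class SampleSizeError(FrameIndepError):
    """Too few observations for the requested statistic."""


class InsufficientCasesError(FrameIndepError):
    """Inter-case sampling needs at least two cases."""


class DegenerateFoldError(FrameIndepError):
    """A cross-validation training fold would contain a single class."""


class ConfigError(FrameIndepError):
    """A run/phantom configuration is inconsistent or incomplete."""
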