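"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers (and the
CLI) can report which stage failed and why instead of surfacing a bare
``ValueError`` from deep inside numpy.
"""


class LipnetError(Exception):
    """Base class for all package errors."""


class InvalidImageError(LipnetError):
    """Image violates the multi-channel data-model invariants."""


class ChannelCountMismatchError(LipnetError):
    """TIFF page count does not match the requested channel names."""


class UnsupportedSampleFormatError(LipnetError):
    """Pixel dtype is not 8- or 16-bit unsigned integer."""


class UnknownFormatError(LipnetError):
    """Unrecognised metrics serialization format."""


class DegenerateFitError(LipnetError):
    """Least-squares fit is undefined (constant regressor)."""


class DegenerateInputError(LipnetError):
    """Input carries too little variation for the requested operation."""


class NonThinSkeletonError(LipnetError):
    """Skeleton classification received input that is not unit-width."""


class PlacementError(LipnetError):
    """Cells could not be placed without overlap at the given image size."""


class NormalizationError(LipnetError):
    """Per-cell normalization applied with an invalid cell count, or twice."""


class ConfigError(LipnetError):
    """Pipeline configuration failed validation."""
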