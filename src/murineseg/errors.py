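"""Exception hierarchy shared across the pipeline."""


class MurinesegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MurinesegError):
    """An image file is missing or carries invalid required metadata."""


class GeometryError(MurinesegError):
    """Phantom geometry cannot be realised on the requested grid."""


class GridMismatchError(MurinesegError):
    """Two volumes/masks that must share a grid do not."""


class EmptyMaskError(MurinesegError):
    """An operation that needs foreground voxels received an empty mask."""


class DegenerateInputError(MurinesegError):
    """Input carries no usable signal (e.g. a constant volume)."""


class UndefinedMetricError(MurinesegError):
    """A metric is undefined for the given inputs (e.g. HD on an empty mask)."""


class ArchitectureError(MurinesegError):
    """Input shape or weight set is incompatible with the network layout."""


class RegistrationError(MurinesegError):
    """Image registration failed to produce a usable transform."""
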