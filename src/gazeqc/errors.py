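"""Exception hierarchy shared across the package."""


class GazeQCError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GazeQCError, ValueError):
    """Invalid generation or conversion parameters (non-positive rate, zero resolution, ...)."""


class GeometryError(GazeQCError):
    """Scene geometry is unusable, e.g. the screen falls outside the camera field of view."""


class MarkersNotFound(GazeQCError):
    """Fewer than five candidate regions were found in a scene frame."""


class AmbiguousDetection(GazeQCError):
    """Marker clusters are too close together to assign identities reliably."""


class DegenerateGeometry(GazeQCError):
    """Coincident detected points or zero apparent size make a ratio undefined."""


class DomainError(GazeQCError, ValueError):
    """Input outside the mathematical domain of an operation."""


class EmptyTrial(GazeQCError):
    """A recording with zero samples where at least one is required."""


class InsufficientData(GazeQCError):
    """Too few valid samples (or valid sample pairs) to compute a statistic."""
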