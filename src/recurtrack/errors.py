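"""Exception hierarchy shared across the package."""


class RecurtrackError(Exception):
    """Base class for all package-specific errors."""


class GridIncompatibilityError(RecurtrackError):
    """Two volumes that must share a grid do not."""


class BoundsError(RecurtrackError):
    """A requested geometric object does not fit inside the volume grid."""


class DegenerateMaskError(RecurtrackError):
    """A lesion mask is empty where a non-empty one is required."""


class EmptyMaskError(DegenerateMaskError):
    """Operation needs at least one lesion voxel (e.g. a centroid)."""


class InvalidDirectionError(RecurtrackError):
    """A direction vector is zero or otherwise unusable."""


class ConfigurationError(RecurtrackError):
    """A configuration value violates a stated precondition."""


class EmptyROIError(RecurtrackError):
    """Tracking was asked to seed or terminate in an empty region."""


class DegenerateStreamlineError(RecurtrackError):
    """A streamline has fewer than two points or coincident endpoints."""


class UndefinedDirectionError(DegenerateStreamlineError):
    """Streamline endpoints coincide; no representative direction exists."""


class UndefinedCorrelationError(RecurtrackError):
    """A vector has zero variance across components; Pearson r is undefined."""


class UndefinedVectorError(RecurtrackError):
    """A progression vector is undefined (coincident centroids)."""


class InsufficientDataError(RecurtrackError):
    """Not enough observations for the requested statistic."""


class FormatError(RecurtrackError):
    """A file does not conform to its declared format."""


class UnsupportedFormatError(FormatError):
    """File extension is not a recognized tractogram format."""
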