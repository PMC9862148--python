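"""Exception hierarchy used across the package."""


class TwinscopeError(Exception):
    """Base class for all package-specific errors."""


class CohortError(TwinscopeError):
    """Family cohort does not have the expected composition or roles."""


class ConfigError(TwinscopeError):
    """A simulation or pipeline configuration value is out of range."""


class GeometryError(TwinscopeError):
    """A requested mask geometry does not fit the voxel grid."""


class ValidationError(TwinscopeError):
    """An input table violates its schema (duplicates, missing hemis, ...)."""


class InsufficientDataError(TwinscopeError):
    """Too few items to compute a statistic."""


class DegenerateDataError(TwinscopeError):
    """Zero between-item variance: the statistic is undefined."""


class StandardizationError(TwinscopeError):
    """Composite alpha reference smaller than a subject's slice count."""


class EmptyMaskError(TwinscopeError):
    """A mask volume contains no foreground voxels."""


class EmptyDistributionError(TwinscopeError):
    """No foreground pixels left after applying the background rule."""
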