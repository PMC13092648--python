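"""Exception types shared across the package."""


class IhmtquantError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(IhmtquantError):
    """Volumes do not share a common grid (shape / voxel size)."""


class InvalidSpecError(IhmtquantError):
    """A synthetic-data specification violates its invariants."""


class EmptyRegionError(IhmtquantError):
    """A requested region contains no usable pixels/voxels."""


class NoCollagenError(IhmtquantError):
    """No collagen pixels found; collagen-type fractions are undefined."""


class DegenerateFitError(IhmtquantError):
    """A regression fit is degenerate (e.g. all abscissae identical)."""


class SelectionError(IhmtquantError):
    """Protocol selection cannot proceed (e.g. every acquisition excluded)."""


class ConfigurationError(IhmtquantError):
    """An analysis configuration is internally inconsistent."""


class ManifestError(IhmtquantError):
    """A study manifest is missing entries or references missing files."""
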