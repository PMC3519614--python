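"""Exception hierarchy shared across the pipeline."""


class DatspectError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(DatspectError, ValueError):
    """Phantom or grid geometry is degenerate or inconsistent."""


class FormatError(DatspectError, ValueError):
    """An image file is not a readable NIfTI-1 / Analyze 7.5 volume."""


class HeaderError(FormatError):
    """An image header is internally inconsistent or truncated."""


class TransformError(DatspectError, ValueError):
    """A spatial transform is singular or otherwise unusable."""


class NormalizationError(DatspectError, ValueError):
    """Count normalization cannot be performed (e.g. zero maximum)."""


class ReferenceRegionError(DatspectError, ValueError):
    """The nonspecific (reference) region mean is non-positive."""


class ConfigError(DatspectError, ValueError):
    """A run configuration contains unknown or invalid keys."""
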