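"""Exception types shared across the package."""


class OroshiftError(Exception):
    """Base class for all package-specific errors."""


class EmptyClipError(OroshiftError):
    """A boundary polygon contains no cell centers of the grid."""


class DisjointGridsError(OroshiftError):
    """Two grids (or a grid and a boundary) do not overlap."""


class DegenerateSampleError(OroshiftError):
    """A statistic was requested on a sample too small or too flat to support it."""


class TemperatureInversionError(OroshiftError):
    """Fitted lapse rate is non-negative; an upslope shift distance is undefined."""


class ConfigError(OroshiftError):
    """Invalid run or generator configuration."""
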