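"""Exception hierarchy shared across the package."""


class PartialScanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PartialScanError):
    """A file could not be decoded in the requested raster format."""


class ChannelError(FormatError):
    """A multi-channel raster was supplied where a single channel is required."""


class ValidationError(PartialScanError):
    """Payload violates an invariant (non-finite pixels, non-rectangular grid)."""


class StateError(PartialScanError):
    """Operation applied to a HeightMap in the wrong normalization state."""


class DimensionError(PartialScanError):
    """Shape mismatch between images, masks or model inputs."""


class ParameterError(PartialScanError):
    """Degenerate or out-of-range parameter value."""


class InfeasibleMaskError(ParameterError):
    """No line mask satisfies the requested (m, p, pattern) constraints."""


class ConfigurationError(PartialScanError):
    """Inconsistent model / training configuration."""


class CorrectionError(PartialScanError):
    """A flagged scan line has no clean neighbours to correct from."""


class MetricError(PartialScanError):
    """A metric is undefined for the given input (constant image, zero spectrum)."""


class DataError(PartialScanError):
    """Empty or malformed dataset passed to training/evaluation."""
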