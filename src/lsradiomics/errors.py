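"""Exception hierarchy shared across the package."""


class LsRadiomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LsRadiomicsError):
    """Invalid parameter values or geometry (bad specs, ROI out of bounds, ...)."""


class ImageFormatError(LsRadiomicsError):
    """Unreadable, truncated, multi-frame, or color image input."""


class EstimationError(LsRadiomicsError):
    """Automatic boundary-gradient estimation failed; set I0 manually."""


class MetricError(LsRadiomicsError):
    """An evaluation metric is undefined for the given masks (e.g. empty reference)."""


class NumericalError(LsRadiomicsError):
    """Divergence or non-finite values during curve evolution."""
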