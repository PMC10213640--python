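"""Exception hierarchy used across the pipeline."""


class AdcTextureError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdcTextureError, ValueError):
    """An invalid parameter value (probability outside [0,1], width <= 0, ...)."""


class FormatError(AdcTextureError, ValueError):
    """A file that cannot be interpreted as the expected volume/table format."""


class GeometryError(AdcTextureError, ValueError):
    """Mismatched voxel grids where congruence is required (no resampling)."""


class DegenerateProblemError(AdcTextureError, ValueError):
    """A statistically degenerate input, e.g. a single-class label vector."""


class InputError(AdcTextureError, ValueError):
    """Malformed numeric input to a model (non-finite features, wrong width)."""
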