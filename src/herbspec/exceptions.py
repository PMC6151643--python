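"""Exception hierarchy for the herbspec pipeline."""


class HerbspecError(Exception):
    """Base class for all package errors."""


class AxisError(HerbspecError):
    """Invalid spectral axis construction or lookup."""


class AxisRangeError(AxisError):
    """Requested wavelength lies too far outside the axis."""


class DegenerateReferenceError(HerbspecError):
    """White and dark reference frames do not satisfy white > dark."""


class NoSampleError(HerbspecError):
    """Segmentation found no foreground object."""


class SceneGeometryError(HerbspecError):
    """Sample ellipses overlap or fall outside the frame."""


class DegenerateResponseError(HerbspecError):
    """Response vector is constant; regression is undefined."""


class SelectionError(HerbspecError):
    """A wavelength selector received an invalid configuration."""


class ConfigError(HerbspecError):
    """A run configuration failed validation."""
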