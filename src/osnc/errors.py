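"""Exception hierarchy shared across the package."""


class OSNCError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OSNCError, ValueError):
    """Invalid configuration or specification values."""


class ParameterError(OSNCError, ValueError):
    """A numeric parameter is outside its valid range."""


class ShapeError(OSNCError, ValueError):
    """Array shapes are inconsistent."""


class InputError(OSNCError, ValueError):
    """Empty or otherwise unusable input data."""


class ImageIOError(OSNCError, IOError):
    """Reading or writing an image file failed."""


class DegenerateClassError(OSNCError, RuntimeError):
    """A fuzzy class collapsed (zero total weight or zero deviation)."""
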