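"""Exception types raised across the package.

All inherit from :class:`CapsenhanceError` so callers (and the CLI) can catch
everything the library raises with one clause; each also inherits the closest
builtin so existing ``except ValueError`` style code keeps working.
"""


class CapsenhanceError(Exception):
    """Base class for all errors raised by capsenhance."""


class ParameterError(CapsenhanceError, ValueError):
    """A numeric parameter is outside its documented valid range."""


class SizeError(CapsenhanceError, ValueError):
    """An image has the wrong shape, or two images disagree in shape."""


class GeometryError(CapsenhanceError, ValueError):
    """Requested scene geometry does not fit in the requested dimensions."""


class FormatError(CapsenhanceError, ValueError):
    """An image file has an unsupported layout, dtype or extension."""


class ConfigError(CapsenhanceError, ValueError):
    """A configuration file is malformed or holds out-of-range values."""


class UndefinedStatisticError(CapsenhanceError, ZeroDivisionError):
    """A relative-change statistic is undefined (zero reference std/mean)."""
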