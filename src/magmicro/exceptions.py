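"""Package-wide exceptions and warnings."""


class MagmicroError(Exception):
    """Base class for magmicro errors."""


class ConfigError(MagmicroError, ValueError):
    """Invalid configuration or construction argument."""


class SingularityError(MagmicroError, ValueError):
    """Field requested at (or numerically at) a dipole's own location."""


class InitializationError(MagmicroError, RuntimeError):
    """Cold-start search failed to find a converging two-bead state."""


class StreamFormatError(MagmicroError, ValueError):
    """Malformed field-stream or length-series file."""


class AlignmentError(MagmicroError, ValueError):
    """Time alignment impossible (e.g. no overlapping support)."""


class AlignmentWarning(UserWarning):
    """Alignment optimum is weakly determined (near-flat objective)."""
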