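"""Exception hierarchy for coastalghg."""


class CoastalGHGError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CoastalGHGError, ValueError):
    """An argument violates a precondition (wrong sign, empty, malformed)."""


class RangeError(InvalidInputError):
    """A physical quantity lies outside the validity range of a fitted
    coefficient set; extrapolation is refused rather than silently applied."""


class ConfigurationError(CoastalGHGError, ValueError):
    """A configuration value is inconsistent with the data or another setting."""


class StructuralFormatError(CoastalGHGError, ValueError):
    """An input stream violates the expected structure (e.g. the water/air
    phase alternation of equilibrator measurement cycles)."""
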