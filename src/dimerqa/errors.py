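"""Exception hierarchy used across the package."""


class DimerQAError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DimerQAError, ValueError):
    """A structure or confidence record could not be parsed (missing field, bad format)."""


class ConsistencyError(DimerQAError, ValueError):
    """Structure and confidence record disagree (length/token mismatch)."""


class EmptyInterfaceError(DimerQAError, ValueError):
    """An interface-dependent quantity was requested for a model without inter-chain contacts."""


class CalibrationError(DimerQAError, ValueError):
    """Calibration input is degenerate (single class, constant score, rank deficiency)."""
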