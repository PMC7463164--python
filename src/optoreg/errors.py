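"""Exception hierarchy shared across the package."""


class OptoregError(Exception):
    """Base class for all package errors."""


class FormatError(OptoregError):
    """A file could not be parsed; the message names the offending record."""


class ValidationError(OptoregError):
    """Input data violates a documented invariant."""


class FrameMismatchError(ValidationError):
    """Coordinate data from different frames was combined."""


class DegenerateFitError(ValidationError):
    """A transform fit is ill-posed (e.g. coplanar landmarks, singular matrix)."""


class CapPackingError(OptoregError):
    """A synthetic cap layout could not satisfy its channel-count contract."""
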