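"""Exception and warning types shared across the package."""


class MyovisError(Exception):
    """Base class for all package errors."""


class SignalParseError(MyovisError):
    """A signal file could not be parsed (names the offending line)."""


class SignalFormatError(MyovisError):
    """A signal file violates the expected layout (e.g. jittery time base)."""


class DegenerateEpochError(MyovisError):
    """An epoch cannot be normalized (zero peak) or is too short."""


class InvariantViolationError(MyovisError):
    """A matrix or record violates a structural invariant (e.g. asymmetry)."""


class UndefinedMeasureWarning(UserWarning):
    """A network measure is undefined for this graph; NaN is returned."""
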