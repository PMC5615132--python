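"""Exception types shared across the package."""


class LimnomagError(Exception):
    """Base class for all package errors."""


class FormatError(LimnomagError):
    """A file does not conform to the documented table dialect."""


class ValidationError(LimnomagError):
    """Parsed content violates a domain invariant."""


class UndefinedStatisticError(LimnomagError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
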