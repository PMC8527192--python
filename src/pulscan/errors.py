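"""Exception and warning hierarchy."""


class PulscanError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PulscanError):
    """A malformed input file.

    Carries the offending line number when one is known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ModelConfigError(PulscanError):
    """A PUL model configuration file violates the documented schema."""


class InputError(PulscanError):
    """Invalid or inconsistent user-supplied data."""


class AdapterMissingError(PulscanError):
    """An optional external tool (gene caller, HMM scanner) is unavailable."""


class PulscanWarning(UserWarning):
    """Non-fatal data issues (e.g. unreferenced protein sequences)."""
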