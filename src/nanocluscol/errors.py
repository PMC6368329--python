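"""Exception hierarchy shared across the package."""


class NanocluscolError(Exception):
    """Base class for all package errors."""


class FormatError(NanocluscolError):
    """A file does not have the expected structure (e.g. a mapped column is missing)."""


class ParseError(NanocluscolError):
    """A specific row of an input file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ValidationError(NanocluscolError):
    """An argument violates a precondition or invariant."""


class ConfigError(NanocluscolError):
    """An analysis configuration is inconsistent or incomplete."""
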