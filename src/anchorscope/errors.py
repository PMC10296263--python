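"""Exception hierarchy.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` to exit code 3; everything else is a bug.
"""


class AnchorscopeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AnchorscopeError):
    """A config value is missing, out of range, or inconsistent."""


class DataError(AnchorscopeError):
    """Input data are malformed or violate a precondition."""


class DataFormatError(DataError):
    """A file could not be parsed; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
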