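"""Exception types shared across the package."""


class CisbindError(Exception):
    """Base class for all package-specific errors."""


class MotifParseError(CisbindError):
    """Raised when a motif file cannot be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(CisbindError):
    """Raised when a data structure violates its invariants."""


class StructureError(CisbindError):
    """Raised for malformed or incomplete protein-DNA complex coordinates."""
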