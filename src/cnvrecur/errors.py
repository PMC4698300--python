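"""Exception types shared across the pipeline."""


class CnvRecurError(Exception):
    """Base class for all pipeline errors."""


class ParseError(CnvRecurError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(CnvRecurError):
    """Input parsed but violates a structural invariant."""


class DegenerateInputError(CnvRecurError):
    """Statistically degenerate input (zero variance, empty set, ...)."""
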