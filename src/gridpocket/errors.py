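"""Exception hierarchy for gridpocket."""


class GridPocketError(Exception):
    """Base class for all gridpocket errors."""


class ParseError(GridPocketError):
    """A structure file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TypingError(GridPocketError):
    """An atom type could not be resolved against the force-field table."""
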