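"""Exception hierarchy.

``ValidationError`` signals bad user input (CLI exit code 1);
``ParseError`` signals a malformed input file and always names the
file and line; anything else is a runtime failure (exit code 2).
"""


class FallmineError(Exception):
    """Base class for all package errors."""


class ValidationError(FallmineError):
    """Invalid configuration, parameters, or database contents."""


class ParseError(FallmineError):
    """A malformed row or header in an input CSV."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
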