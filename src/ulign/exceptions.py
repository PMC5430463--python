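"""Exception hierarchy shared across the package."""


class UlignError(Exception):
    """Base class for all package-specific errors."""


class ParseError(UlignError):
    """A file could not be parsed in the stated dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class MappingError(UlignError):
    """An alignment violates injectivity or references unknown nodes."""


class UndefinedScoreError(UlignError):
    """A score's denominator is empty; the value is missing, not zero."""
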