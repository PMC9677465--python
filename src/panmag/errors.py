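"""Exception types shared across the package."""


class PanmagError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PanmagError):
    """An invalid parameter combination was supplied."""


class ParseError(PanmagError):
    """A dataset file could not be parsed.

    Carries the offending file and line number where known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
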