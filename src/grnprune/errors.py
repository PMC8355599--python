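"""Exception types."""


class GrnpruneError(Exception):
    """Base class for package errors."""


class ParseError(GrnpruneError):
    """A malformed input file; carries the offending location when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConfigurationError(GrnpruneError):
    """Inconsistent or incomplete user configuration."""


class ZeroVarianceTarget(GrnpruneError):
    """Raised when a target gene has constant expression and cannot be pruned."""
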