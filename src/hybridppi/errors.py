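"""Exception hierarchy shared across the package.

Validation errors signal bad user input (CLI exit code 2); runtime errors
signal data/processing failures (CLI exit code 3).
"""


class HybridPPIError(Exception):
    """Base class for all package errors."""


class ValidationError(HybridPPIError, ValueError):
    """Input violates a documented precondition."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class DisconnectedGraphError(ValidationError):
    """Diffusion states were requested on a disconnected graph."""


class CalibrationError(HybridPPIError, RuntimeError):
    """Hybrid-weight calibration failed; carries fit diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
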