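"""Exception hierarchy shared by all modules."""


class LovspecError(Exception):
    """Base class for all package errors."""


class ValidationError(LovspecError, ValueError):
    """Invalid argument or malformed in-memory data."""


class SpectralRangeError(ValidationError):
    """Requested wavelength/field/time lies outside the data range."""


class ParseError(LovspecError, ValueError):
    """Malformed input file."""


class FitError(LovspecError, RuntimeError):
    """A least-squares fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
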