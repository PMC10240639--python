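"""Exception hierarchy shared across the pipeline."""


class PFJForceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PFJForceError):
    """Invalid configuration or design parameters; names the offending field."""


class ModelError(PFJForceError):
    """Invalid or inconsistent musculoskeletal model definition."""


class InputError(PFJForceError):
    """Invalid numerical input to an operation."""


class AlignmentError(InputError):
    """Time bases of two series do not match."""


class NoStanceError(InputError):
    """No sample of the force record exceeds the stance threshold."""


class GapError(InputError):
    """A marker gap is too long to interpolate across."""


class InsufficientHistoryError(InputError):
    """A trajectory does not cover the requested pre-contact window."""


class ParseError(PFJForceError):
    """Malformed input file; carries a line number where available."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class MetricsUnavailableError(PFJForceError):
    """All frames of a trial were flagged; no metrics can be extracted."""
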