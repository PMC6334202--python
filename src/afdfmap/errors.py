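"""Exception hierarchy shared across the pipeline."""


class AfdfmapError(Exception):
    """Base class for all package errors."""


class ValidationError(AfdfmapError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(AfdfmapError, IOError):
    """A file could not be read or does not match its declared format."""


class AlignmentError(AfdfmapError, RuntimeError):
    """Reference-lead cross-correlation too weak to trust an alignment."""


class UndefinedOIError(AfdfmapError, ZeroDivisionError):
    """Organization index undefined (zero total spectral power)."""


class FitError(AfdfmapError, RuntimeError):
    """Nonlinear least-squares fit failed to converge."""

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals
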