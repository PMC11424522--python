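"""Exception hierarchy shared across the package."""


class GrowthRefError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GrowthRefError, ValueError):
    """A mathematically invalid input (outside the function's domain)."""


class ValidationError(GrowthRefError, ValueError):
    """A structurally invalid input (bad schema, bad option, bad spec)."""


class SchemaError(ValidationError):
    """A delimited-text file does not match the expected column layout."""


class ConvergenceError(GrowthRefError, RuntimeError):
    """The likelihood optimiser failed to converge.

    Carries the last iterate so callers can inspect where it stalled.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
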