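"""Exception hierarchy shared across the package."""


class RespiroxError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RespiroxError, ValueError):
    """A physical quantity is outside its valid domain."""


class ConfigError(RespiroxError, ValueError):
    """An inconsistent or invalid configuration was supplied."""


class FitError(RespiroxError, RuntimeError):
    """A regression or optimisation failed to produce a usable result.

    Carries the last iterate (if any) in :attr:`last_params`.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class MetricsError(RespiroxError, ValueError):
    """Insufficient or unusable data for a metabolic endpoint."""
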