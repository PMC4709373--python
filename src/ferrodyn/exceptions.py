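"""Exception hierarchy used across the package."""


class FerrodynError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FerrodynError, ValueError):
    """An argument violates a documented precondition (e.g. negative weight)."""


class ComputationalError(FerrodynError, RuntimeError):
    """A numerical routine failed (integrator breakdown, no root bracket, ...)."""


class ValidationError(FerrodynError, ValueError):
    """A dataset or configuration file failed validation."""


class ConfigError(ValidationError):
    """A configuration file contains unknown keys or ill-typed values."""
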