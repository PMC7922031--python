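"""Exception hierarchy shared across the package."""


class PbpkError(Exception):
    """Base class for all package errors."""


class ValidationError(PbpkError, ValueError):
    """A value violates a documented precondition or invariant."""


class ConfigurationError(PbpkError):
    """A configuration file or record is incomplete or inconsistent."""


class SchemaError(ConfigurationError):
    """A config file does not match the documented schema."""


class AssemblyError(PbpkError):
    """The ODE system could not be assembled (unresolved references)."""


class IntegrationError(PbpkError):
    """The ODE solver failed or produced an unphysical state."""
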