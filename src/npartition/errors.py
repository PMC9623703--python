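"""Exception and warning types shared across the package."""


class NPartitionError(ValueError):
    """Base class for all package-specific errors."""


class InvalidArgumentError(NPartitionError):
    """An argument violates a documented precondition."""


class DegenerateInputError(NPartitionError):
    """Input has no usable variation (e.g. all x identical)."""


class InsufficientSupportError(NPartitionError):
    """No candidate breakpoint has enough points on both sides."""


class InsufficientReplicationError(NPartitionError):
    """A treatment group has too few animals for the mixed model."""


class SchemaError(NPartitionError):
    """A tabular input does not match the versioned record schema."""


class ConfigError(NPartitionError):
    """A configuration file is missing or misuses a key."""


class ImplausibleValueWarning(UserWarning):
    """A computed quantity is physically implausible (e.g. negative urine N)."""
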