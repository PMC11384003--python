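"""Exception hierarchy shared across the package."""


class NscnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NscnetError):
    """Input table is malformed (missing columns, unparseable values)."""


class ValidationError(NscnetError):
    """Input parsed but violates a domain invariant."""


class DanglingEndpointError(ValidationError):
    """An edge references a neuron id absent from the annotation table."""


class AmbiguityError(NscnetError):
    """A cluster-to-subtype assignment is contradictory."""


class ConfigError(NscnetError):
    """A simulation or run configuration is infeasible."""
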