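"""Exception types shared across the package."""


class PhosphosigError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(PhosphosigError):
    """A file or record violates the expected external format."""


class DesignError(PhosphosigError):
    """The sample design table violates a structural invariant (e.g. pairing)."""


class ConfigError(PhosphosigError):
    """A configuration value is outside its documented domain or infeasible."""
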