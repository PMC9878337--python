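"""Exception hierarchy shared across the package."""


class RadeError(Exception):
    """Base class for all package-specific errors."""


class InputError(RadeError):
    """Malformed, inconsistent, or contract-violating input data."""


class ConfigError(RadeError):
    """Invalid configuration or threshold choice."""
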