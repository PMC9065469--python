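"""Exception hierarchy shared across pipeline stages."""


class FibronetError(Exception):
    """Base class for all package errors."""


class ConfigError(FibronetError):
    """Invalid configuration: unknown key, out-of-range threshold, bad format."""


class InputError(FibronetError):
    """Invalid or unusable input data (missing columns, empty library, ...)."""


class ContractError(FibronetError):
    """A caller violated a documented precondition."""
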