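"""Exception hierarchy shared across the pipeline."""


class CnpipeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CnpipeError, ValueError):
    """An input violates an operation's precondition."""


class ConfigurationError(CnpipeError, ValueError):
    """A configuration value is inconsistent or physically impossible."""


class OutOfRangeError(CnpipeError, ValueError):
    """A requested value lies outside the achievable range."""


class EncodingError(CnpipeError, ValueError):
    """A stimulus schedule cannot be rendered as analog signals."""
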