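"""Exception types shared across the package."""


class PpgStressError(ValueError):
    """Base class for all package-specific errors."""


class ParseError(PpgStressError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(PpgStressError):
    """A table is missing or carrying unexpected columns."""


class ConfigError(PpgStressError):
    """A configuration key is unknown or violates an invariant."""
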