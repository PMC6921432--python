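"""Exception types shared across the package."""


class SialonetError(Exception):
    """Base class for all package errors."""


class ConfigError(SialonetError, ValueError):
    """A configuration object violates its invariants."""


class ValidationError(SialonetError, ValueError):
    """An input file or in-memory object violates a data contract."""
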