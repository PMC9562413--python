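"""Exception types shared across the package."""


class CufflessError(Exception):
    """Base class for all package errors."""


class FormatError(CufflessError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class DataError(CufflessError, ValueError):
    """Input data violate a precondition (non-monotone time, empty channel, ...)."""


class ConfigError(CufflessError, ValueError):
    """A configuration value is invalid or inconsistent."""
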