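class MetabotimeError(Exception):
    """Base class for all package errors."""


class ConfigError(MetabotimeError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(MetabotimeError, ValueError):
    """Malformed or inconsistent input data; the message locates the problem."""
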