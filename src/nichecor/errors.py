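"""Exception types.

``ConfigError`` marks a bad user configuration (CLI exit code 2);
``DataError`` marks invalid or inconsistent input data (CLI exit code 3).
"""


class NichecorError(Exception):
    """Base class for all package errors."""


class ConfigError(NichecorError):
    """Invalid configuration or parameter combination."""


class DataError(NichecorError):
    """Invalid, inconsistent, or unusable input data."""
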