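"""Exception hierarchy shared by all modules.

``ConfigurationError`` marks invalid user-supplied configuration (CLI exit
code 2); ``DataError`` marks invalid or inconsistent data (CLI exit code 3).
"""


class PatternSpectraError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PatternSpectraError):
    """A configuration value violates its documented constraints."""


class DataError(PatternSpectraError):
    """Input data are malformed, inconsistent, or unusable."""
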