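"""Exception hierarchy.

``ConfigurationError`` marks a problem with how the caller set things up
(missing columns, bad flags); ``DataError`` marks a problem with the data
itself (duplicate keys, wrong scale, impossible values).
"""


class DianovaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DianovaError):
    """The caller's configuration (column mapping, flags, paths) is invalid."""


class DataError(DianovaError):
    """The data violates an invariant (duplicates, scale, sign, coverage)."""
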