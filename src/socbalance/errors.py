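"""Exception hierarchy with CLI exit codes.

Exit codes: 0 success, 2 schema error (malformed table layout),
3 data error (values violating invariants), 4 config error.
"""


class SocBalanceError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(SocBalanceError):
    """A table is missing required columns or has an unusable layout."""

    exit_code = 2


class DataError(SocBalanceError):
    """A value violates a domain invariant (depths, signs, matching)."""

    exit_code = 3


class ConfigError(SocBalanceError):
    """A run-configuration value is out of its admissible range."""

    exit_code = 4
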