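"""Exception hierarchy shared across the package.

ValidationError maps to CLI exit code 2, DataError to exit code 3.
"""


class LncSubLocError(Exception):
    """Base class for package errors."""


class ValidationError(LncSubLocError, ValueError):
    """A contract violation in arguments or configuration."""


class DataError(LncSubLocError, ValueError):
    """Malformed or inconsistent input data."""
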