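"""Exception hierarchy shared by all coroperf modules.

``ValidationError`` covers bad inputs (CLI exit code 2), ``NumericalError``
covers solver failures (CLI exit code 3).
"""


class CoroperfError(Exception):
    """Base class for all package errors."""


class ValidationError(CoroperfError, ValueError):
    """Input outside its physiological/structural domain."""


class SchemaError(ValidationError):
    """A file does not match the expected schema; names the field and file."""


class NumericalError(CoroperfError, RuntimeError):
    """A solver failed to converge or produced an inconsistent result."""
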