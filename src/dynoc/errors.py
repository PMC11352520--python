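"""Exception hierarchy.

Three error families map onto distinct CLI exit codes: bad arguments
(ParameterError, exit 2), malformed or inconsistent data (StructuralError,
exit 3) and numerically degenerate inputs (NumericalError, exit 4).
"""


class DynocError(Exception):
    """Base class for all package errors."""


class ParameterError(DynocError, ValueError):
    """An argument value is outside its documented domain."""


class StructuralError(DynocError, ValueError):
    """Input data is malformed: shape/label mismatches, missing values."""


class NumericalError(DynocError, ArithmeticError):
    """A computation is degenerate (e.g. zero-variance series)."""
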