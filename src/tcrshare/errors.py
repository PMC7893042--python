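"""Exception hierarchy.

Distinct classes map to distinct CLI exit codes (argument / format / data / I/O),
so callers can tell a bad parameter from a bad input file.
"""


class TcrShareError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ArgumentError(TcrShareError, ValueError):
    """A parameter is outside its documented domain."""

    exit_code = 2


class FormatError(TcrShareError):
    """An input file does not conform to the expected tabular format."""

    exit_code = 3


class MissingColumnError(FormatError):
    """A mandatory column is absent from an input table."""

    def __init__(self, column: str, path: str = "") -> None:
        self.column = column
        super().__init__(f"missing mandatory column {column!r}"
                         + (f" in {path}" if path else ""))


class EmptyInputError(FormatError):
    """An input table contains no rows."""


class DataError(TcrShareError):
    """Input rows are structurally valid but semantically inconsistent."""

    exit_code = 4


class EmptyRepertoireError(DataError):
    """No productive records remain to build a clonotype table from."""


class DegenerateInputError(DataError):
    """A statistic is undefined on this input (e.g. zero pooled variance)."""
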