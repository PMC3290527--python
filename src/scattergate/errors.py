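"""Exception hierarchy.

Every parse error raised while reading a text input carries the 1-based line
number of the offending line in its message.
"""


class ScatterGateError(Exception):
    """Base class for all package errors."""


class FormatError(ScatterGateError):
    """Malformed input file (ragged row, bad field, empty file, ...)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DuplicateIdentifierError(FormatError):
    """A gene identifier occurred more than once under the 'error' policy."""


class GeometryError(ScatterGateError):
    """Invalid polygon (too few vertices, non-finite coordinates, ...)."""


class MappingError(ScatterGateError):
    """A channel mapping names a measurement the table does not have."""


class ScaleError(ScatterGateError):
    """Invalid color/size scale range (v_min >= v_max, bad radii, ...)."""


class EmptyPlotError(ScatterGateError):
    """No point survives missing-value exclusion for the requested mapping."""


class DomainError(ScatterGateError):
    """Statistical parameter outside its valid domain."""
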