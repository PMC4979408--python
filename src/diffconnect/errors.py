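"""Exception hierarchy.

All package errors derive from :class:`DiffConnectError` so callers can
catch broadly; format-level problems additionally derive from ``ValueError``.
"""


class DiffConnectError(Exception):
    """Base class for all diffconnect errors."""


class FormatError(DiffConnectError, ValueError):
    """A file does not conform to its declared format."""


class DimensionError(FormatError):
    """Declared and actual dimensions of a matrix file disagree."""


class CellParseError(FormatError):
    """A data cell could not be parsed; carries row/column location."""

    def __init__(self, message: str, row: int | None = None, column: int | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class ProbeConflictError(FormatError):
    """The same probe id maps to two different gene symbols."""


class ClassCountError(DiffConnectError, ValueError):
    """A two-class contrast was requested on a non-two-class phenotype."""


class SignatureSizeError(DiffConnectError, ValueError):
    """A ranked list is too short for the requested signature size."""


class EmptyOverlapError(DiffConnectError, ValueError):
    """A query gene set shares no genes with the ranked list."""


class DegenerateQueryError(DiffConnectError, ValueError):
    """A query gene set covers the entire ranked list (no misses possible)."""


class StructureError(DiffConnectError, ValueError):
    """A compound structure could not be parsed; carries the offending string."""

    def __init__(self, smiles: str, message: str | None = None):
        super().__init__(message or f"unparseable structure: {smiles!r}")
        self.smiles = smiles


class JoinError(DiffConnectError, ValueError):
    """An id-based join failed (e.g. duplicate instance ids)."""


class ValidationError(DiffConnectError, ValueError):
    """An in-memory object violates its invariants."""
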