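"""Exception hierarchy for the floralri analysis pipeline."""

from __future__ import annotations


class FloralRIError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FloralRIError):
    """A tabular input violates the expected CSV schema.

    Carries enough context (file, row, column) for a user to locate the
    offending cell.
    """

    def __init__(self, message: str, *, file: str | None = None,
                 row: int | None = None, column: str | None = None):
        self.file = file
        self.row = row
        self.column = column
        where = []
        if file is not None:
            where.append(f"file={file!r}")
        if row is not None:
            where.append(f"row={row}")
        if column is not None:
            where.append(f"column={column!r}")
        suffix = f" [{', '.join(where)}]" if where else ""
        super().__init__(message + suffix)


class SeasonMismatchError(FloralRIError):
    """Two phenology series from different seasons were compared."""


class NoFloweringError(FloralRIError):
    """The focal species never flowered in the season: no mating
    opportunities, so the temporal index is undefined."""


class UndefinedIndexError(FloralRIError):
    """H + C = 0: the isolation index is undefined (distinct from
    complete isolation, which requires C > 0)."""


class MissingBaselineError(FloralRIError):
    """A heterospecific cross lacks the conspecific baseline needed to
    compute an index."""
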