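"""Tab-separated user tables with exact content preservation.

User data arrives as plain headered ``.txt`` files, tab-separated, columns in
any order.  Every workflow in this package consumes and returns a
:class:`DataTable`, and the central contract is that the structure and content
of user-provided data survive every operation: cells are opaque strings, never
reinterpreted, and original columns stay leftmost in their original order.
New information is only ever *appended* as extra columns (or extra rows, for
multi-hit expansion).

Dialect: UTF-8, tab as the only separator, no quoting.  Both ``\\n`` and
``\\r\\n`` are accepted on read; ``\\n`` is written.  An embedded tab inside a
cell is unrepresentable and writing such a cell is an error.  The empty string
is the universal missing-value representation in outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "DataTable",
    "TableError",
    "read_table",
    "write_table",
    "append_columns",
    "expand_rows",
]


class TableError(ValueError):
    """A user table violates the tab-separated contract."""


def dedup_labels(labels: Sequence[str]) -> list[str]:
    """Make labels unique by suffixing ``.1``, ``.2``... on repeats."""
    seen: dict[str, int] = {}
    out: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = 0
            out.append(lab)
        else:
            seen[lab] += 1
            cand = f"{lab}.{seen[lab]}"
            while cand in seen:
                seen[lab] += 1
                cand = f"{lab}.{seen[lab]}"
            seen[cand] = 0
            out.append(cand)
    return out


@dataclass(frozen=True)
class DataTable:
    """A rectangular table of strings with an ordered, unique header.

    Parameters
    ----------
    header
        Ordered column labels; unique (callers should pass through
        :func:`dedup_labels` if collisions are possible).
    rows
        One list of cell strings per row, each exactly ``len(header)`` long.
    provenance
        Source path, or ``"derived"`` for tables produced by a workflow.
    """

    header: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    provenance: str = "derived"

    def __post_init__(self) -> None:
        if len(set(self.header)) != len(self.header):
            raise TableError(f"duplicate header labels: {list(self.header)}")
        n = len(self.header)
        for i, row in enumerate(self.rows):
            if len(row) != n:
                raise TableError(
                    f"row {i} has {len(row)} cells, header has {n}"
                )

    @classmethod
    def from_rows(
        cls,
        header: Iterable[str],
        rows: Iterable[Iterable[str]],
        provenance: str = "derived",
    ) -> "DataTable":
        return cls(
            header=tuple(header),
            rows=tuple(tuple(r) for r in rows),
            provenance=provenance,
        )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.header)

    def column_index(self, label: str) -> int:
        try:
            return self.header.index(label)
        except ValueError:
            raise TableError(
                f"column {label!r} not in header {list(self.header)}"
            ) from None

    def column(self, label: str) -> list[str]:
        i = self.column_index(label)
        return [row[i] for row in self.rows]

    def row_mapping(self, index: int) -> dict[str, str]:
        """One row as a header→cell mapping."""
        return dict(zip(self.header, self.rows[index]))

    def project(self, labels: Sequence[str]) -> "DataTable":
        """Select columns by label, preserving row order."""
        idx = [self.column_index(l) for l in labels]
        return DataTable.from_rows(
            labels, ([row[i] for i in idx] for row in self.rows)
        )


def read_table(path: str | Path) -> DataTable:
    """Read a headered tab-separated file verbatim.

    The first line is the header.  Duplicate header labels are deduplicated
    with the ``.1`` suffix rule (warning logged).  Rows shorter than the
    header are padded with empty cells; a row longer than the header is fatal
    because silently dropping user cells would violate content preservation.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    # normalize line endings; drop a single trailing newline, keep interior
    # blank lines as empty rows is not useful -> skip fully blank lines
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise TableError(f"{path}: empty file, no header line")
    raw_header = lines[0].split("\t")
    header = dedup_labels([h.strip() for h in raw_header])
    if header != [h.strip() for h in raw_header]:
        log.warning("%s: duplicate header labels deduplicated", path)
    n = len(header)
    rows: list[tuple[str, ...]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        cells = line.split("\t")
        if len(cells) > n:
            raise TableError(
                f"{path}: row at line {lineno} has {len(cells)} cells "
                f"but header has {n}"
            )
        if len(cells) < n:
            cells = cells + [""] * (n - len(cells))
        rows.append(tuple(cells))
    return DataTable(header=tuple(header), rows=tuple(rows), provenance=str(path))


def write_table(table: DataTable, path: str | Path) -> None:
    """Write a table as UTF-8 TSV with ``\\n`` line endings."""
    path = Path(path)
    for lab in table.header:
        if "\t" in lab:
            raise TableError(f"embedded tab in header label {lab!r}")
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(table.header) + "\n")
        for row in table.rows:
            for cell in row:
                if "\t" in cell:
                    raise TableError(f"embedded tab in cell {cell!r}")
            fh.write("\t".join(row) + "\n")


def append_columns(
    table: DataTable,
    new_labels: Sequence[str],
    values_per_row: Sequence[Sequence[str]],
) -> DataTable:
    """Append columns to the right edge; original columns untouched.

    ``values_per_row`` supplies one value list (``len(new_labels)`` long) per
    existing row.  Labels colliding with the existing header are suffixed.
    """
    if len(values_per_row) != table.n_rows:
        raise TableError(
            f"got {len(values_per_row)} value lists for {table.n_rows} rows"
        )
    k = len(new_labels)
    for i, vals in enumerate(values_per_row):
        if len(vals) != k:
            raise TableError(f"row {i}: expected {k} new values, got {len(vals)}")
    header = tuple(dedup_labels(list(table.header) + list(new_labels)))
    rows = tuple(
        tuple(row) + tuple(vals) for row, vals in zip(table.rows, values_per_row)
    )
    return DataTable(header=header, rows=rows, provenance="derived")


def expand_rows(
    table: DataTable,
    row_index: int,
    replacement_rows: Sequence[Sequence[str]],
) -> DataTable:
    """Replace one row in place by one or more rows.

    The relative order of all other rows is preserved.  An empty replacement
    list keeps the original row (a zero-hit row is never deleted); callers
    wanting blank appended cells pass them explicitly in the replacement.
    """
    if not 0 <= row_index < table.n_rows:
        raise TableError(f"row index {row_index} out of range")
    if not replacement_rows:
        return table
    repl = tuple(tuple(r) for r in replacement_rows)
    for r in repl:
        if len(r) != table.n_cols:
            raise TableError(
                f"replacement row has {len(r)} cells, table has {table.n_cols}"
            )
    rows = table.rows[:row_index] + repl + table.rows[row_index + 1 :]
    return replace(table, rows=rows, provenance="derived")
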