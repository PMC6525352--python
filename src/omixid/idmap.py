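"""Add-identifiers and integrate-tables workflows.

Two capabilities built on :mod:`omixid.refdata` and :mod:`omixid.tables`:

* :func:`add_identifiers` — append chosen identifier columns onto a user
  table, resolving each row through up to three identifier columns tried
  left-to-right as a *fallback chain* (the first non-empty cell that resolves
  wins; later columns are not consulted).  Species restrictions apply
  separately to input and output; a cross-species output restriction routes
  each hit through Ensembl-pivot ortholog links.

* :func:`integrate_tables` — merge two tables on up to three key columns per
  side, either by plain string equality or by identifier *conversion*, where
  both sides are projected into a shared keyspace of Ensembl gene IDs
  (bridged across species by ortholog links) and matched there.  All
  user-provided content is preserved: unmatched rows are retained with the
  other side blank unless the intersection is requested.

Multiple hits per row are handled by a :class:`MatchPolicy`: return the first
hit (default), pipe-join all hits into the row, or expand one output row per
hit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .refdata import GeneRecord, XrefStore, RefDataError, SUPPORTED_ID_TYPES, normalize_id
from .tables import DataTable, TableError, dedup_labels

__all__ = [
    "ColumnSpec",
    "MatchPolicy",
    "resolve_row",
    "add_identifiers",
    "integrate_tables",
    "OUTPUT_PSEUDO_TYPES",
]

#: extra appendable columns beyond the identifier namespaces
OUTPUT_PSEUDO_TYPES = ("tax_id", "description")

#: delimiter for multiple values in one cell (NCBI synonym-list convention)
JOIN_DELIM = "|"


@dataclass(frozen=True)
class ColumnSpec:
    """Binds a table column to an identifier namespace.

    ``id_type`` may be ``None`` only in string-equality merges, where cells
    are compared verbatim after whitespace trimming.
    """

    column_label: str
    id_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id_type is not None and self.id_type not in SUPPORTED_ID_TYPES:
            raise RefDataError(
                f"unsupported id_type {self.id_type!r} for column "
                f"{self.column_label!r}"
            )


class MatchPolicy(str, enum.Enum):
    """How a row with multiple hits is rendered.

    FIRST keeps the first hit in canonical order (the default); JOIN_IN_ROW
    pipe-joins distinct values, preserving row count; EXPAND_ROWS emits one
    output row per hit.
    """

    FIRST = "first"
    JOIN_IN_ROW = "join"
    EXPAND_ROWS = "expand"


def _check_specs(table: DataTable, specs: Sequence[ColumnSpec], *, need_types: bool) -> None:
    if not 1 <= len(specs) <= 3:
        raise TableError(f"between 1 and 3 key columns required, got {len(specs)}")
    labels = [s.column_label for s in specs]
    if len(set(labels)) != len(labels):
        raise TableError(f"duplicate key columns: {labels}")
    for s in specs:
        table.column_index(s.column_label)  # fatal before any work
        if need_types and s.id_type is None:
            raise TableError(
                f"conversion requires an id_type for column {s.column_label!r}"
            )


def resolve_row(
    store: XrefStore,
    row: Mapping[str, str],
    specs: Sequence[ColumnSpec],
    in_tax: Optional[Iterable[int]] = None,
    out_tax: Optional[Iterable[int]] = None,
) -> list[GeneRecord]:
    """Resolve one row to gene records via the fallback chain.

    Specs are tried left-to-right; the first whose cell is non-empty *and*
    yields at least one record (after the input-species filter) fixes the hit
    set — it is a fallback, not a union.  With an output-species restriction
    that excludes a hit's taxon, the hit is projected through ortholog links
    into the requested taxa; without any restriction the direct hits are
    returned.  Results are in canonical record order; an unresolvable row
    yields an empty list.
    """
    in_taxa = None if in_tax is None else set(in_tax)
    out_taxa = None if out_tax is None else set(out_tax)
    hits: list[GeneRecord] = []
    for spec in specs:
        cell = row.get(spec.column_label, "").strip()
        if not cell or spec.id_type is None:
            continue
        hits = store.lookup(spec.id_type, cell, in_taxa)
        if hits:
            break
    if not hits or out_taxa is None:
        return hits
    projected: list[GeneRecord] = []
    seen: set[int] = set()
    for rec in hits:
        if rec.tax_id in out_taxa:
            candidates = [rec]
        else:
            candidates = []
            for gene in sorted(rec.ensembl_gene):
                for tax in sorted(out_taxa):
                    if tax == rec.tax_id:
                        continue
                    for partner in store.orthologs(gene, tax):
                        candidates.extend(store.lookup("ensembl_gene", partner, [tax]))
        for cand in candidates:
            if id(cand) not in seen:
                seen.add(id(cand))
                projected.append(cand)
    return sorted(projected, key=GeneRecord.sort_key)


def _record_values(rec: GeneRecord, out_type: str) -> list[str]:
    if out_type == "tax_id":
        return [str(rec.tax_id)]
    if out_type == "description":
        return [rec.description] if rec.description else []
    return rec.values_of(out_type)


def add_identifiers(
    store: XrefStore,
    table: DataTable,
    specs: Sequence[ColumnSpec],
    out_types: Sequence[str],
    in_tax: Optional[Iterable[int]] = None,
    out_tax: Optional[Iterable[int]] = None,
    policy: MatchPolicy = MatchPolicy.FIRST,
) -> DataTable:
    """Append one identifier column per requested type onto ``table``.

    ``out_types`` draws from the supported namespaces plus the ``tax_id`` and
    ``description`` pseudo-types.  Original columns are preserved leftmost in
    order; under EXPAND_ROWS a multi-hit row becomes several rows sharing its
    original cells, and a zero-hit row is kept with blank appended cells.
    """
    if not out_types:
        raise TableError("at least one output identifier type required")
    for t in out_types:
        if t not in SUPPORTED_ID_TYPES and t not in OUTPUT_PSEUDO_TYPES:
            raise RefDataError(f"unsupported output type {t!r}")
    _check_specs(table, specs, need_types=True)
    policy = MatchPolicy(policy)

    new_header = tuple(dedup_labels(list(table.header) + list(out_types)))
    out_rows: list[tuple[str, ...]] = []
    for row_cells in table.rows:
        row = dict(zip(table.header, row_cells))
        hits = resolve_row(store, row, specs, in_tax, out_tax)
        if policy is MatchPolicy.EXPAND_ROWS:
            if not hits:
                out_rows.append(row_cells + ("",) * len(out_types))
            else:
                for rec in hits:
                    appended = tuple(
                        JOIN_DELIM.join(_record_values(rec, t)) for t in out_types
                    )
                    out_rows.append(row_cells + appended)
        elif policy is MatchPolicy.FIRST:
            first = hits[0] if hits else None
            appended = tuple(
                (_record_values(first, t)[0] if first and _record_values(first, t) else "")
                for t in out_types
            )
            out_rows.append(row_cells + appended)
        else:  # JOIN_IN_ROW
            appended = []
            for t in out_types:
                vals: list[str] = []
                for rec in hits:
                    for v in _record_values(rec, t):
                        if v not in vals:
                            vals.append(v)
                appended.append(JOIN_DELIM.join(vals))
            out_rows.append(row_cells + tuple(appended))
    return DataTable(header=new_header, rows=tuple(out_rows), provenance="derived")


# ---------------------------------------------------------------------------
# table integration


def _string_keys(row: Mapping[str, str], specs: Sequence[ColumnSpec]) -> frozenset[str]:
    keys = set()
    for spec in specs:
        cell = row.get(spec.column_label, "").strip()
        if not cell:
            continue
        if spec.id_type is not None:
            keys.add((spec.id_type, normalize_id(spec.id_type, cell)))
        else:
            keys.add(("raw", cell))
    return frozenset(keys)


def _conversion_keys(
    store: XrefStore,
    row: Mapping[str, str],
    specs: Sequence[ColumnSpec],
    out_taxa: Optional[set[int]],
) -> frozenset[str]:
    """Project a row into the canonical Ensembl-gene keyspace.

    The row's hits contribute their Ensembl genes plus the ortholog partners
    of those genes, so two rows from different species match exactly when
    their genes are linked through the Ensembl pivot.
    """
    hits = resolve_row(store, row, specs)
    keys: set[str] = set()
    for rec in hits:
        for gene in rec.ensembl_gene:
            keys.add(gene)
            for partner, tax in store._ortho.get(gene, ()):
                if out_taxa is None or tax in out_taxa:
                    keys.add(partner)
    return frozenset(keys)


def integrate_tables(
    store: Optional[XrefStore],
    table_a: DataTable,
    table_b: DataTable,
    keys_a: Sequence[ColumnSpec],
    keys_b: Sequence[ColumnSpec],
    mode: str = "conversion",
    out_tax: Optional[Iterable[int]] = None,
    intersection_only: bool = False,
) -> DataTable:
    """Merge two user tables on identifier keys.

    In ``string-equality`` mode a row pair matches when any key cell of A
    equals any key cell of B (after trimming, and case-folding for symbol
    columns).  In ``conversion`` mode both rows are resolved through the
    cross-reference store and match when they share at least one canonical
    Ensembl gene key, with ortholog links bridging species.  Matched pairs
    produce one output row per (a, b) pair; unmatched rows are retained with
    the other side blank unless ``intersection_only``.
    """
    if mode not in ("conversion", "string-equality"):
        raise TableError(f"unknown merge mode {mode!r}")
    need_types = mode == "conversion"
    if need_types and store is None:
        raise TableError("conversion mode requires a cross-reference store")
    _check_specs(table_a, keys_a, need_types=need_types)
    _check_specs(table_b, keys_b, need_types=need_types)
    out_taxa = None if out_tax is None else set(out_tax)

    def keys_of(table: DataTable, specs: Sequence[ColumnSpec], cells: tuple) -> frozenset:
        row = dict(zip(table.header, cells))
        if mode == "string-equality":
            return _string_keys(row, specs)
        return _conversion_keys(store, row, specs, out_taxa)

    a_keys = [keys_of(table_a, keys_a, r) for r in table_a.rows]
    b_keys = [keys_of(table_b, keys_b, r) for r in table_b.rows]

    bucket: dict[object, list[int]] = {}
    for j, ks in enumerate(b_keys):
        for k in ks:
            bucket.setdefault(k, []).append(j)

    header = tuple(dedup_labels(list(table_a.header) + list(table_b.header)))
    blank_a = ("",) * table_a.n_cols
    blank_b = ("",) * table_b.n_cols
    out_rows: list[tuple[str, ...]] = []
    b_matched: set[int] = set()
    for i, row_a in enumerate(table_a.rows):
        js: set[int] = set()
        for k in a_keys[i]:
            js.update(bucket.get(k, ()))
        if js:
            for j in sorted(js):
                b_matched.add(j)
                out_rows.append(row_a + table_b.rows[j])
        elif not intersection_only:
            out_rows.append(row_a + blank_b)
    if not intersection_only:
        for j, row_b in enumerate(table_b.rows):
            if j not in b_matched:
                out_rows.append(blank_a + row_b)
    return DataTable(header=header, rows=tuple(out_rows), provenance="derived")
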