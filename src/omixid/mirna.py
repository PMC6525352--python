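"""miRNA name normalization and multi-database target queries.

Mature miRNA names drift between miRBase releases (``hsa-miR-124`` became
``hsa-miR-124-3p`` when arms were split), so every query first normalizes the
user's names to their current miRBase-style name via an alias table keyed on
the stable MIMAT accession.  Target interactions come from four flat-file
databases — three predictive (``microcosm``, ``microrna_org``,
``targetscan``, each with a score) and one experimentally validated
(``mirtarbase``, no score) — and a consensus filter keeps (miRNA, gene)
pairs supported by at least *k* of the selected databases.

Both query directions are provided: forward (miRNA → target genes) and
reverse (gene → targeting miRNAs), with the same database selection and
support filter applied symmetrically.  Gene identity across databases is
decided on resolved Entrez IDs; rows lacking Entrez are resolved through the
gene cross-reference store when one is supplied, and rows that still share
no key are counted as distinct genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .idmap import ColumnSpec, MatchPolicy, JOIN_DELIM
from .refdata import XrefStore, normalize_id
from .tables import DataTable, TableError, dedup_labels

log = logging.getLogger(__name__)

__all__ = [
    "TARGET_DBS",
    "VALIDATED_DBS",
    "MiRNARecord",
    "MirnaNameStore",
    "NameResolution",
    "TargetStore",
    "load_mirbase",
    "load_target_dbs",
    "normalize_mirna",
    "query_targets",
    "reverse_lookup",
    "merge_with_expression",
    "convert_mirna_column",
]

#: the four target databases, in canonical column order
TARGET_DBS = ("microcosm", "microrna_org", "targetscan", "mirtarbase")
#: databases of experimentally validated interactions (no score)
VALIDATED_DBS = frozenset({"mirtarbase"})


@dataclass
class MiRNARecord:
    """A mature miRNA: current name, accessions, history, sequence."""

    current_name: str
    mature_accession: str
    stemloop_accession: str
    tax_id: int
    mature_sequence: str
    aliases: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class NameResolution:
    """Outcome of normalizing one miRNA name.

    ``status`` is ``exact`` (already the current name), ``alias`` (resolved
    through history), ``ambiguous`` (the alias names several accessions;
    candidates listed, nothing silently chosen) or ``unresolved``.
    """

    input_name: str
    status: str
    current_name: str = ""
    mature_accession: str = ""
    candidates: tuple[str, ...] = ()


class MirnaNameStore:
    """miRBase-style name store: accession-keyed records plus alias index."""

    def __init__(self) -> None:
        self.records: dict[str, MiRNARecord] = {}
        self._current: dict[str, set[str]] = {}  # casefolded name -> accessions
        self._alias: dict[str, set[str]] = {}
        self.ambiguous_aliases: set[str] = set()

    def add_record(self, rec: MiRNARecord) -> None:
        if rec.mature_accession in self.records:
            raise TableError(f"duplicate mature accession {rec.mature_accession}")
        self.records[rec.mature_accession] = rec
        self._current.setdefault(rec.current_name.casefold(), set()).add(rec.mature_accession)

    def add_alias(self, accession: str, alias: str) -> None:
        key = alias.strip().casefold()
        if not key:
            return
        bucket = self._alias.setdefault(key, set())
        bucket.add(accession)
        if accession in self.records:
            self.records[accession].aliases.add(alias.strip())
        if len(bucket) > 1:
            self.ambiguous_aliases.add(key)


def load_mirbase(aliases_path: str | Path, mature_path: str | Path) -> MirnaNameStore:
    """Load the mature-miRNA table and the accession→aliases history.

    ``mature_path``: headered TSV (name, accession, stemloop_accession,
    tax_id, sequence).  ``aliases_path``: headered TSV (accession,
    semicolon-joined historical names).  An alias naming two accessions is
    recorded under both and flagged ambiguous — never silently resolved.
    """
    store = MirnaNameStore()
    mature_path, aliases_path = Path(mature_path), Path(aliases_path)
    with mature_path.open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            name, acc, stem, tax, seq = line.split("\t")
            store.add_record(MiRNARecord(
                current_name=name.strip(), mature_accession=acc.strip(),
                stemloop_accession=stem.strip(), tax_id=int(tax),
                mature_sequence=seq.strip()))
    with aliases_path.open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            acc, names = line.split("\t")
            for alias in names.split(";"):
                if alias.strip():
                    store.add_alias(acc.strip(), alias)
    return store


def normalize_mirna(
    name_store: MirnaNameStore,
    name: str,
    species_restrict: Optional[Iterable[int]] = None,
) -> NameResolution:
    """Resolve one miRNA name to its current miRBase-style name.

    Matching is case-insensitive; an exact current-name match wins over an
    alias match; the species restriction filters candidates *before* the
    status is assigned, so a zebrafish-only name under a human restriction is
    unresolved rather than cross-species.
    """
    raw = name.strip()
    if not raw:
        return NameResolution(input_name=name, status="unresolved")
    key = raw.casefold()
    taxa = None if species_restrict is None else set(species_restrict)

    def tax_ok(acc: str) -> bool:
        rec = name_store.records.get(acc)
        return rec is not None and (taxa is None or rec.tax_id in taxa)

    exact = sorted(a for a in name_store._current.get(key, ()) if tax_ok(a))
    if len(exact) == 1:
        rec = name_store.records[exact[0]]
        return NameResolution(raw, "exact", rec.current_name, rec.mature_accession)
    if len(exact) > 1:
        return NameResolution(raw, "ambiguous", candidates=tuple(exact))
    via_alias = sorted(a for a in name_store._alias.get(key, ()) if tax_ok(a))
    if len(via_alias) == 1:
        rec = name_store.records[via_alias[0]]
        return NameResolution(raw, "alias", rec.current_name, rec.mature_accession)
    if len(via_alias) > 1:
        return NameResolution(raw, "ambiguous", candidates=tuple(via_alias))
    return NameResolution(raw, "unresolved")


# ---------------------------------------------------------------------------
# target store


@dataclass
class _GeneInfo:
    entrez: str = ""
    symbol: str = ""
    ensembl_gene: str = ""

    def merge(self, other: "_GeneInfo") -> None:
        self.entrez = self.entrez or other.entrez
        self.symbol = self.symbol or other.symbol
        self.ensembl_gene = self.ensembl_gene or other.ensembl_gene


class TargetStore:
    """(mature miRNA, gene, database) interactions with dual indices."""

    def __init__(self) -> None:
        # (accession, gene_key) -> {db: score-or-None}
        self.pairs: dict[tuple[str, tuple], dict[str, Optional[float]]] = {}
        self.gene_info: dict[tuple, _GeneInfo] = {}
        self.by_mirna: dict[str, set[tuple]] = {}
        self.by_gene: dict[tuple, set[str]] = {}
        # identifier value -> gene_keys, for reverse lookup entry points
        self.gene_id_index: dict[tuple[str, str], set[tuple]] = {}
        self.db_counts: dict[str, int] = {}
        self.unresolved_rows: dict[str, int] = {}

    def _index_gene(self, key: tuple, info: _GeneInfo) -> None:
        for id_type, val in (("entrez", info.entrez), ("symbol", info.symbol),
                             ("ensembl_gene", info.ensembl_gene)):
            if val:
                self.gene_id_index.setdefault(
                    (id_type, normalize_id(id_type, val)), set()).add(key)

    def add(self, accession: str, info: _GeneInfo, db: str,
            score: Optional[float], key: tuple) -> None:
        slot = self.pairs.setdefault((accession, key), {})
        if db in slot:
            # duplicate (m, g) within one db (e.g. per-transcript rows):
            # collapse keeping the largest-magnitude score
            old = slot[db]
            if score is not None and (old is None or abs(score) > abs(old)):
                slot[db] = score
        else:
            slot[db] = score
            self.db_counts[db] = self.db_counts.get(db, 0) + 1
        if key in self.gene_info:
            self.gene_info[key].merge(info)
        else:
            self.gene_info[key] = info
        self.by_mirna.setdefault(accession, set()).add(key)
        self.by_gene.setdefault(key, set()).add(accession)
        self._index_gene(key, self.gene_info[key])


def _gene_key(info: _GeneInfo, xref_store: Optional[XrefStore],
              tax_id: int, fallback: object) -> tuple:
    """Cross-database gene identity: resolved Entrez wins; otherwise try the
    cross-reference store; otherwise Ensembl gene, then symbol, then a
    per-row token (counted as distinct)."""
    if not info.entrez and xref_store is not None:
        for id_type, val in (("ensembl_gene", info.ensembl_gene), ("symbol", info.symbol)):
            if not val:
                continue
            recs = xref_store.lookup(id_type, val, [tax_id])
            if recs and recs[0].entrez_id:
                info.entrez = recs[0].entrez_id
                break
    if info.entrez:
        return ("entrez", tax_id, info.entrez)
    if info.ensembl_gene:
        return ("ensembl_gene", tax_id, info.ensembl_gene)
    if info.symbol:
        return ("symbol", tax_id, info.symbol.casefold())
    return ("row", tax_id, fallback)


def load_target_dbs(
    paths: Mapping[str, str | Path],
    name_store: MirnaNameStore,
    xref_store: Optional[XrefStore] = None,
) -> TargetStore:
    """Load one headered TSV per database into a :class:`TargetStore`.

    Columns: mature_name_or_accession, tax_id, entrez, symbol, ensembl_gene,
    score.  miRNA names are normalized to accessions on the way in; rows
    whose name cannot be resolved are counted and skipped.  Validated
    databases carry no score.
    """
    store = TargetStore()
    for db, path in paths.items():
        if db not in TARGET_DBS:
            raise TableError(f"unknown target database {db!r}")
        path = Path(path)
        with path.open(encoding="utf-8") as fh:
            fh.readline()
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\r\n")
                if not line:
                    continue
                mature, tax_s, entrez, symbol, ensg, score_s = line.split("\t")
                tax = int(tax_s)
                mature = mature.strip()
                if mature.upper().startswith("MIMAT"):
                    acc = mature.upper()
                else:
                    res = normalize_mirna(name_store, mature, [tax])
                    if res.status in ("unresolved", "ambiguous"):
                        store.unresolved_rows[db] = store.unresolved_rows.get(db, 0) + 1
                        continue
                    acc = res.mature_accession
                def clean(cell: str) -> str:
                    c = cell.strip()
                    return "" if c == "-" else c

                info = _GeneInfo(entrez=clean(entrez), symbol=clean(symbol),
                                 ensembl_gene=clean(ensg))
                score = None
                if db not in VALIDATED_DBS and score_s.strip() not in ("", "-"):
                    score = float(score_s)
                key = _gene_key(info, xref_store, tax, (db, lineno))
                store.add(acc, info, db, score, key)
    return store


# ---------------------------------------------------------------------------
# queries


def _supported_pairs(
    target_store: TargetStore,
    accession: str,
    selected_dbs: Sequence[str],
    min_support: int,
) -> list[tuple[tuple, dict[str, Optional[float]], int]]:
    out = []
    sel = set(selected_dbs)
    for key in target_store.by_mirna.get(accession, ()):
        dbs = target_store.pairs[(accession, key)]
        present = {d: s for d, s in dbs.items() if d in sel}
        if len(present) >= min_support:
            out.append((key, present, len(present)))
    out.sort(key=lambda t: t[0])
    return out


def _check_support(selected_dbs: Sequence[str], min_support: int) -> None:
    if not selected_dbs:
        raise TableError("at least one target database must be selected")
    for db in selected_dbs:
        if db not in TARGET_DBS:
            raise TableError(f"unknown target database {db!r}")
    if not 1 <= min_support <= len(selected_dbs):
        raise TableError(
            f"min_support={min_support} outside 1..{len(selected_dbs)} "
            f"for {len(selected_dbs)} selected databases"
        )


def _gene_columns(info: _GeneInfo, xref_store: Optional[XrefStore],
                  tax_id: int, append_gene_ids: bool) -> tuple[str, str, str]:
    entrez, symbol, ensg = info.entrez, info.symbol, info.ensembl_gene
    if append_gene_ids and xref_store is not None and not (entrez and symbol and ensg):
        for id_type, val in (("entrez", entrez), ("ensembl_gene", ensg), ("symbol", symbol)):
            if not val:
                continue
            recs = xref_store.lookup(id_type, val, [tax_id])
            if recs:
                rec = recs[0]
                entrez = entrez or (rec.entrez_id or "")
                symbol = symbol or (rec.symbol or "")
                ensg = ensg or (min(rec.ensembl_gene) if rec.ensembl_gene else "")
                break
    return entrez, symbol, ensg


def query_targets(
    target_store: TargetStore,
    name_store: MirnaNameStore,
    mirna_names: Sequence[str],
    selected_dbs: Sequence[str] = TARGET_DBS,
    min_support: int = 1,
    species: Optional[Iterable[int]] = None,
    append_gene_ids: bool = False,
    xref_store: Optional[XrefStore] = None,
) -> DataTable:
    """Forward query: target genes of each miRNA with k-of-n support.

    One output row per (mature miRNA, target gene) pair whose support count —
    the number of selected databases asserting the pair — is at least
    ``min_support``.  Names are normalized first; an unresolved or ambiguous
    input name yields one row with its status and blank target columns, so
    no input is silently dropped.
    """
    _check_support(selected_dbs, min_support)
    header = [
        "input_name", "current_name", "mature_accession", "stemloop_accession",
        "mature_sequence", "status", "gene_entrez", "gene_symbol",
        "gene_ensembl", "support",
    ]
    for db in selected_dbs:
        header.append(f"in_{db}")
    for db in selected_dbs:
        if db not in VALIDATED_DBS:
            header.append(f"{db}_score")
    score_dbs = [db for db in selected_dbs if db not in VALIDATED_DBS]

    rows: list[tuple[str, ...]] = []
    for raw in mirna_names:
        res = normalize_mirna(name_store, raw, species)
        if res.status in ("unresolved", "ambiguous"):
            note = JOIN_DELIM.join(res.candidates) if res.candidates else ""
            rows.append(tuple([res.input_name, note, "", "", "", res.status]
                              + [""] * (len(header) - 6)))
            continue
        rec = name_store.records[res.mature_accession]
        hits = _supported_pairs(target_store, res.mature_accession,
                                selected_dbs, min_support)
        if not hits:
            rows.append(tuple([res.input_name, rec.current_name, rec.mature_accession,
                               rec.stemloop_accession, rec.mature_sequence, res.status]
                              + [""] * (len(header) - 6)))
            continue
        for key, present, support in hits:
            info = target_store.gene_info[key]
            entrez, symbol, ensg = _gene_columns(info, xref_store, rec.tax_id,
                                                 append_gene_ids)
            cells = [res.input_name, rec.current_name, rec.mature_accession,
                     rec.stemloop_accession, rec.mature_sequence, res.status,
                     entrez, symbol, ensg, str(support)]
            for db in selected_dbs:
                cells.append("1" if db in present else "0")
            for db in score_dbs:
                s = present.get(db)
                cells.append("" if s is None else format(s, "g"))
            rows.append(tuple(cells))
    return DataTable(header=tuple(header), rows=tuple(rows), provenance="derived")


def reverse_lookup(
    target_store: TargetStore,
    name_store: MirnaNameStore,
    gene_table: DataTable,
    gene_keys: Sequence[ColumnSpec],
    selected_dbs: Sequence[str] = TARGET_DBS,
    min_support: int = 1,
    xref_store: Optional[XrefStore] = None,
    policy: MatchPolicy = MatchPolicy.EXPAND_ROWS,
) -> DataTable:
    """Reverse query: miRNAs targeting each gene of a user table.

    Gene key columns follow the same fallback semantics as identifier
    addition: the first non-empty cell that reaches a known gene wins.  The
    database selection and support filter mirror the forward query exactly.
    A row whose keys resolve to nothing is retained with blank miRNA cells.
    """
    _check_support(selected_dbs, min_support)
    if not 1 <= len(gene_keys) <= 3:
        raise TableError(f"between 1 and 3 gene key columns required, got {len(gene_keys)}")
    for spec in gene_keys:
        gene_table.column_index(spec.column_label)
        if spec.id_type is None:
            raise TableError(f"gene key {spec.column_label!r} needs an id_type")
    policy = MatchPolicy(policy)
    sel = set(selected_dbs)

    new_labels = ["mirna_name", "mirna_accession", "mirna_support"]
    header = tuple(dedup_labels(list(gene_table.header) + new_labels))
    out_rows: list[tuple[str, ...]] = []
    for row_cells in gene_table.rows:
        row = dict(zip(gene_table.header, row_cells))
        keys: set[tuple] = set()
        for spec in gene_keys:
            cell = row.get(spec.column_label, "").strip()
            if not cell:
                continue
            found = set(target_store.gene_id_index.get(
                (spec.id_type, normalize_id(spec.id_type, cell)), ()))
            if not found and xref_store is not None:
                # translate through the cross-reference store, then retry
                for rec in xref_store.lookup(spec.id_type, cell):
                    for id_type, vals in (
                        ("entrez", [rec.entrez_id] if rec.entrez_id else []),
                        ("ensembl_gene", sorted(rec.ensembl_gene)),
                        ("symbol", [rec.symbol] if rec.symbol else []),
                    ):
                        for v in vals:
                            found |= target_store.gene_id_index.get(
                                (id_type, normalize_id(id_type, v)), set())
            if found:
                keys = found
                break
        hits: list[tuple[str, int]] = []  # (accession, support)
        for key in sorted(keys):
            for acc in target_store.by_gene.get(key, ()):
                present = [d for d in target_store.pairs[(acc, key)] if d in sel]
                if len(present) >= min_support:
                    hits.append((acc, len(present)))
        hits = sorted(set(hits), key=lambda h: (name_store.records[h[0]].current_name
                                                if h[0] in name_store.records else h[0]))
        def name_of(acc: str) -> str:
            rec = name_store.records.get(acc)
            return rec.current_name if rec else acc

        if policy is MatchPolicy.EXPAND_ROWS:
            if not hits:
                out_rows.append(row_cells + ("", "", ""))
            else:
                for acc, sup in hits:
                    out_rows.append(row_cells + (name_of(acc), acc, str(sup)))
        elif policy is MatchPolicy.FIRST:
            if hits:
                acc, sup = hits[0]
                out_rows.append(row_cells + (name_of(acc), acc, str(sup)))
            else:
                out_rows.append(row_cells + ("", "", ""))
        else:  # JOIN_IN_ROW
            out_rows.append(row_cells + (
                JOIN_DELIM.join(name_of(a) for a, _ in hits),
                JOIN_DELIM.join(a for a, _ in hits),
                JOIN_DELIM.join(str(s) for _, s in hits),
            ))
    return DataTable(header=header, rows=tuple(out_rows), provenance="derived")


def merge_with_expression(
    interaction_table: DataTable,
    expression_table: DataTable,
    gene_keys_interactions: Sequence[ColumnSpec],
    gene_keys_expression: Sequence[ColumnSpec],
    xref_store: XrefStore,
    intersection_only: bool = False,
) -> DataTable:
    """Attach experimental expression columns to predicted-target rows.

    Delegates to conversion-mode table integration within one species:
    interaction rows gain the expression columns of genes whose resolved
    Ensembl keys match.
    """
    from .idmap import integrate_tables

    return integrate_tables(
        xref_store, interaction_table, expression_table,
        gene_keys_interactions, gene_keys_expression,
        mode="conversion", intersection_only=intersection_only,
    )


def convert_mirna_column(
    name_store: MirnaNameStore,
    table: DataTable,
    column_label: str,
    species_restrict: Optional[Iterable[int]] = None,
) -> DataTable:
    """Append each row's current miRBase-style name as the final column.

    The appended name cell is empty when the input is unresolved or
    ambiguous; a status column follows it so failures are explicit.
    """
    idx = table.column_index(column_label)
    current: list[list[str]] = []
    for row in table.rows:
        res = normalize_mirna(name_store, row[idx], species_restrict)
        name = res.current_name if res.status in ("exact", "alias") else ""
        current.append([name, res.status])
    from .tables import append_columns

    return append_columns(table, ["current_mirna_name", "mirna_status"], current)
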