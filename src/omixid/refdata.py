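"""Flat-file gene cross-reference store with taxonomy-scoped indices.

Reference data lives in a *bundle*: a directory of headered TSVs emulating
the flat-file snapshots a conversion service keeps of NCBI Gene, Ensembl
cross-references, UniProt ID mappings, plus an Ensembl-pivot ortholog table.
Everything is parsed once into an in-memory :class:`XrefStore` so repeated
lookups during a workflow are dictionary-speed.

Resource dialects (all headered TSV, ``-`` or empty cell = absent):

========================  ====================================================
``genes.tsv``             tax_id, entrez_id, symbol, synonyms (pipe-joined),
                          description
``gene2ensembl.tsv``      tax_id, entrez_id, ensembl_gene, ensembl_transcript,
                          ensembl_protein
``uniprot_map.tsv``       uniprot_acc, id_type, value, tax_id  (rows grouped
                          by accession; entrez / ensembl_gene rows anchor the
                          accession to a gene, symbol rows assert a symbol)
``orthologs.tsv``         gene_a, tax_a, gene_b, tax_b  (Ensembl gene pairs,
                          stored symmetrically)
``refseq.tsv``            tax_id, entrez_id, refseq_acc
========================  ====================================================

Loading records each resource's own facts; cross-resource assertions (an
Ensembl accession asserted for an Entrez gene, a UniProt accession anchored
to a record) are held as pending links and applied by :func:`backfill`, which
fills absent fields without ever overwriting an existing value.  The default
loader runs backfill immediately, so ``load_gene_xrefs(paths)`` yields a
fully cross-filled store; pass ``backfill=False`` to inspect the raw
per-resource state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "XrefStore",
    "RefDataError",
    "SUPPORTED_ID_TYPES",
    "SET_FIELDS",
    "BUNDLE_SCHEMA_VERSION",
    "load_gene_xrefs",
    "load_bundle",
    "lookup",
    "orthologs",
    "backfill",
]

#: Identifier namespaces the store can index and resolve.
SUPPORTED_ID_TYPES = (
    "entrez",
    "symbol",
    "ensembl_gene",
    "ensembl_transcript",
    "ensembl_protein",
    "uniprot",
    "refseq",
)

#: GeneRecord fields that hold sets of accessions.
SET_FIELDS = ("ensembl_gene", "ensembl_transcript", "ensembl_protein", "uniprot", "refseq")

#: Bundle manifest schema this code reads; mixing versions is refused.
BUNDLE_SCHEMA_VERSION = 1

MISSING = {"", "-"}


class RefDataError(RuntimeError):
    """Fatal problem with reference bundle content."""


def _absent(cell: str) -> bool:
    return cell.strip() in MISSING


def normalize_id(id_type: str, value: str) -> str:
    """Normalization rule per namespace.

    Symbols and synonyms are matched case-insensitively (human ``TP53`` vs
    zebrafish ``tp53`` conventions); accession-like IDs are matched
    case-sensitively after whitespace trimming, since accessions have a
    defined case.
    """
    v = value.strip()
    if id_type == "symbol":
        return v.casefold()
    return v


@dataclass
class GeneRecord:
    """One gene's cross-reference bundle.

    ``tax_id`` is always present; at least one of entrez / ensembl_gene /
    symbol / uniprot is non-empty.  ``entrez_id`` is unique per
    (tax_id, entrez_id) within a store.
    """

    tax_id: int
    entrez_id: Optional[str] = None
    symbol: Optional[str] = None
    synonyms: set[str] = field(default_factory=set)
    ensembl_gene: set[str] = field(default_factory=set)
    ensembl_transcript: set[str] = field(default_factory=set)
    ensembl_protein: set[str] = field(default_factory=set)
    uniprot: set[str] = field(default_factory=set)
    refseq: set[str] = field(default_factory=set)
    description: Optional[str] = None

    def values_of(self, id_type: str) -> list[str]:
        """All identifier values this record carries under one namespace."""
        if id_type == "entrez":
            return [self.entrez_id] if self.entrez_id else []
        if id_type == "symbol":
            return [self.symbol] if self.symbol else []
        if id_type in SET_FIELDS:
            return sorted(getattr(self, id_type))
        raise RefDataError(f"unsupported id_type {id_type!r}")

    def sort_key(self) -> tuple:
        """Canonical record ordering: ascending tax, then numeric Entrez
        ascending; records lacking Entrez sort after, by lexicographic first
        Ensembl gene."""
        if self.entrez_id is not None:
            return (self.tax_id, 0, int(self.entrez_id), "")
        first_ens = min(self.ensembl_gene) if self.ensembl_gene else ""
        return (self.tax_id, 1, 0, first_ens)

    def as_tuple(self) -> tuple:
        return (
            self.tax_id,
            self.entrez_id,
            self.symbol,
            tuple(sorted(self.synonyms)),
            tuple(sorted(self.ensembl_gene)),
            tuple(sorted(self.ensembl_transcript)),
            tuple(sorted(self.ensembl_protein)),
            tuple(sorted(self.uniprot)),
            tuple(sorted(self.refseq)),
            self.description,
        )


@dataclass
class _PendingLink:
    """Cross-resource assertion applied during backfill.

    ``match_type``/``match_value`` locate target records; ``fills`` maps
    record fields to asserted values.  ``resource`` drives conflict priority.
    """

    resource: str
    tax_id: Optional[int]
    match_type: str
    match_value: str
    fills: dict[str, str]


# priority for conflicting scalar fields, mirroring source listing order
_RESOURCE_PRIORITY = {"ncbi": 0, "ensembl": 1, "uniprot": 2}


class XrefStore:
    """In-memory cross-reference store over one reference bundle."""

    def __init__(self) -> None:
        self.records: list[GeneRecord] = []
        self._by_key: dict[tuple, GeneRecord] = {}  # (tax, entrez) or (tax, None, ensg)
        self._index: dict[tuple[str, str], list[GeneRecord]] = {}
        self._ortho: dict[str, set[tuple[str, int]]] = {}
        self._gene_tax: dict[str, int] = {}  # ensembl gene -> taxon (from ortholog table)
        self._pending: list[_PendingLink] = []
        self.skipped_rows: dict[str, int] = {}
        self.conflicts: list[str] = []
        self.manifest: Optional[dict] = None

    # -- construction -----------------------------------------------------

    def _get_or_create(self, tax_id: int, entrez_id: Optional[str],
                       ensembl_gene: Optional[str] = None) -> GeneRecord:
        if entrez_id is not None:
            key = (tax_id, entrez_id)
        else:
            key = (tax_id, None, ensembl_gene)
        rec = self._by_key.get(key)
        if rec is None:
            rec = GeneRecord(tax_id=tax_id, entrez_id=entrez_id)
            if ensembl_gene is not None:
                rec.ensembl_gene.add(ensembl_gene)
            self._by_key[key] = rec
            self.records.append(rec)
        return rec

    def rebuild_index(self) -> None:
        self._index = {}
        for rec in self.records:
            for t in SUPPORTED_ID_TYPES:
                for v in rec.values_of(t):
                    self._index.setdefault((t, normalize_id(t, v)), []).append(rec)
            for syn in rec.synonyms:
                # synonyms resolve under the symbol namespace
                key = ("symbol", normalize_id("symbol", syn))
                bucket = self._index.setdefault(key, [])
                if rec not in bucket:
                    bucket.append(rec)

    # -- queries ----------------------------------------------------------

    def lookup(
        self,
        id_type: str,
        value: str,
        tax_filter: Optional[Iterable[int]] = None,
    ) -> list[GeneRecord]:
        """All records carrying ``value`` under ``id_type``, canonical order.

        ``tax_filter=None`` means all taxa.  Unknown values yield an empty
        list; an unsupported id_type is fatal.
        """
        if id_type not in SUPPORTED_ID_TYPES:
            raise RefDataError(
                f"unsupported id_type {id_type!r}; expected one of {SUPPORTED_ID_TYPES}"
            )
        v = normalize_id(id_type, value)
        if not v:
            return []
        hits = self._index.get((id_type, v), [])
        taxa = None if tax_filter is None else set(tax_filter)
        out = [r for r in hits if taxa is None or r.tax_id in taxa]
        return sorted(out, key=GeneRecord.sort_key)

    def orthologs(self, ensembl_gene: str, target_tax: int) -> list[str]:
        """Partner Ensembl genes of ``ensembl_gene`` in ``target_tax``.

        A same-taxon request returns the input unchanged; no links yields an
        empty list.  Links are symmetric by construction.
        """
        gene = ensembl_gene.strip()
        own_tax = self._gene_tax.get(gene)
        if own_tax is None:
            for rec in self._index.get(("ensembl_gene", gene), []):
                own_tax = rec.tax_id
                break
        if own_tax is not None and own_tax == target_tax:
            return [gene]
        return sorted(p for p, t in self._ortho.get(gene, ()) if t == target_tax)

    def canonical_dump(self) -> str:
        """Deterministic serialization for equality/fixpoint checks."""
        recs = sorted((r.as_tuple() for r in self.records))
        ortho = sorted(
            (g, p, t) for g, partners in self._ortho.items() for p, t in partners
        )
        return json.dumps({"records": recs, "orthologs": ortho}, default=list)


# ---------------------------------------------------------------------------
# loading


def _read_resource(path: Path, expected_cols: int, store: XrefStore,
                   name: str) -> list[list[str]]:
    if not path.exists():
        raise RefDataError(f"{name}: reference file not found: {path}")
    rows: list[list[str]] = []
    skipped = 0
    with path.open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return rows
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != expected_cols:
                skipped += 1
                log.warning("%s line %d: expected %d columns, got %d; row skipped",
                            path, lineno, expected_cols, len(cells))
                continue
            rows.append(cells)
    if skipped:
        store.skipped_rows[name] = store.skipped_rows.get(name, 0) + skipped
    return rows


def load_gene_xrefs(
    paths: Mapping[str, str | Path],
    taxa_filter: Optional[Iterable[int]] = None,
    *,
    backfill: bool = True,
) -> XrefStore:
    """Parse reference TSVs into an :class:`XrefStore`.

    ``paths`` maps resource names (``genes``, ``gene2ensembl``,
    ``uniprot_map``, ``orthologs``, ``refseq``) to file paths; resources may
    be omitted.  Rows whose taxon is outside ``taxa_filter`` are dropped
    (``None`` = keep all).  A missing file is fatal with its path; a row with
    the wrong column count is skipped, counted and logged; loading zero
    records is fatal.
    """
    store = XrefStore()
    taxa = None if taxa_filter is None else set(taxa_filter)

    def keep(tax: int) -> bool:
        return taxa is None or tax in taxa

    if "genes" in paths:
        for cells in _read_resource(Path(paths["genes"]), 5, store, "genes"):
            tax_s, entrez, symbol, syns, desc = cells
            tax = int(tax_s)
            if not keep(tax) or _absent(entrez):
                continue
            rec = store._get_or_create(tax, entrez.strip())
            if not _absent(symbol):
                rec.symbol = symbol.strip()
            if not _absent(syns):
                rec.synonyms.update(s for s in syns.split("|") if s.strip())
            if not _absent(desc):
                rec.description = desc.strip()

    if "gene2ensembl" in paths:
        for cells in _read_resource(Path(paths["gene2ensembl"]), 5, store, "gene2ensembl"):
            tax_s, entrez, ensg, enst, ensp = cells
            tax = int(tax_s)
            if not keep(tax):
                continue
            fills = {}
            for fld, val in (("ensembl_gene", ensg), ("ensembl_transcript", enst),
                             ("ensembl_protein", ensp)):
                if not _absent(val):
                    fills[fld] = val.strip()
            if _absent(entrez):
                # Ensembl-only orphan: the row defines a record by itself
                if "ensembl_gene" in fills:
                    rec = store._get_or_create(tax, None, fills["ensembl_gene"])
                    rec.ensembl_transcript.update(
                        [fills["ensembl_transcript"]] if "ensembl_transcript" in fills else [])
                    rec.ensembl_protein.update(
                        [fills["ensembl_protein"]] if "ensembl_protein" in fills else [])
                continue
            store._get_or_create(tax, entrez.strip())
            if fills:
                store._pending.append(_PendingLink(
                    resource="ensembl", tax_id=tax,
                    match_type="entrez", match_value=entrez.strip(), fills=fills))

    if "uniprot_map" in paths:
        by_acc: dict[tuple[str, int], list[tuple[str, str]]] = {}
        for cells in _read_resource(Path(paths["uniprot_map"]), 4, store, "uniprot_map"):
            acc, id_type, value, tax_s = cells
            tax = int(tax_s)
            if not keep(tax) or _absent(acc) or _absent(value):
                continue
            by_acc.setdefault((acc.strip(), tax), []).append((id_type.strip(), value.strip()))
        for (acc, tax), assertions in by_acc.items():
            anchors = [(t, v) for t, v in assertions if t in ("entrez", "ensembl_gene")]
            symbols = [v for t, v in assertions if t == "symbol"]
            for match_type, match_value in anchors:
                fills = {"uniprot": acc}
                if symbols:
                    fills["symbol"] = symbols[0]
                store._pending.append(_PendingLink(
                    resource="uniprot", tax_id=tax,
                    match_type=match_type, match_value=match_value, fills=fills))

    if "refseq" in paths:
        for cells in _read_resource(Path(paths["refseq"]), 3, store, "refseq"):
            tax_s, entrez, acc = cells
            tax = int(tax_s)
            if not keep(tax) or _absent(entrez) or _absent(acc):
                continue
            store._get_or_create(tax, entrez.strip())
            store._pending.append(_PendingLink(
                resource="ncbi", tax_id=tax,
                match_type="entrez", match_value=entrez.strip(),
                fills={"refseq": acc.strip()}))

    if "orthologs" in paths:
        for cells in _read_resource(Path(paths["orthologs"]), 4, store, "orthologs"):
            ga, ta_s, gb, tb_s = cells
            ta, tb = int(ta_s), int(tb_s)
            if ta == tb:
                store.skipped_rows["orthologs"] = store.skipped_rows.get("orthologs", 0) + 1
                log.warning("orthologs: same-taxon link %s-%s skipped", ga, gb)
                continue
            if not (keep(ta) and keep(tb)):
                continue
            ga, gb = ga.strip(), gb.strip()
            store._ortho.setdefault(ga, set()).add((gb, tb))
            store._ortho.setdefault(gb, set()).add((ga, ta))
            store._gene_tax[ga] = ta
            store._gene_tax[gb] = tb

    if not store.records:
        raise RefDataError("zero gene records loaded from bundle")
    store.rebuild_index()
    if backfill:
        globals()["backfill"](store)
    return store


def load_bundle(
    bundle_dir: str | Path,
    taxa_filter: Optional[Iterable[int]] = None,
    *,
    backfill: bool = True,
) -> XrefStore:
    """Load a bundle directory, checking its manifest schema version."""
    d = Path(bundle_dir)
    manifest_path = d / "manifest.json"
    manifest = None
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        ver = manifest.get("schema_version")
        if ver != BUNDLE_SCHEMA_VERSION:
            raise RefDataError(
                f"bundle {d} has manifest schema_version={ver}; "
                f"this build reads version {BUNDLE_SCHEMA_VERSION}"
            )
    paths = {
        name: d / f"{name}.tsv"
        for name in ("genes", "gene2ensembl", "uniprot_map", "orthologs", "refseq")
        if (d / f"{name}.tsv").exists()
    }
    store = load_gene_xrefs(paths, taxa_filter, backfill=backfill)
    store.manifest = manifest
    return store


# ---------------------------------------------------------------------------
# operations (module-level mirrors of store methods, per the public surface)


def lookup(
    store: XrefStore,
    id_type: str,
    value: str,
    tax_filter: Optional[Iterable[int]] = None,
) -> list[GeneRecord]:
    return store.lookup(id_type, value, tax_filter)


def orthologs(store: XrefStore, ensembl_gene: str, target_tax: int) -> list[str]:
    return store.orthologs(ensembl_gene, target_tax)


def backfill(store: XrefStore) -> XrefStore:
    """Apply pending cross-resource assertions to fill absent fields.

    Never overwrites an existing value; a conflicting scalar (e.g. two
    resources asserting different symbols) keeps the higher-priority
    resource's value (NCBI > Ensembl > UniProt) and logs the conflict.
    Running backfill twice changes nothing (fixpoint).
    """
    pendings = sorted(
        store._pending,
        key=lambda p: _RESOURCE_PRIORITY.get(p.resource, 9),
    )
    # A link anchored by an Ensembl gene may only become matchable after an
    # Ensembl link fills that gene onto an Entrez record, so iterate whole
    # passes until the store stops changing (at most a handful of passes).
    prev = None
    while True:
        for link in pendings:
            taxa = [link.tax_id] if link.tax_id is not None else None
            targets = store.lookup(link.match_type, link.match_value, taxa)
            for rec in targets:
                for fld, val in link.fills.items():
                    if fld in SET_FIELDS:
                        getattr(rec, fld).add(val)
                    elif fld == "symbol":
                        if rec.symbol is None:
                            rec.symbol = val
                        elif normalize_id("symbol", rec.symbol) != normalize_id("symbol", val):
                            msg = (f"symbol conflict for tax={rec.tax_id} "
                                   f"entrez={rec.entrez_id}: kept {rec.symbol!r}, "
                                   f"{link.resource} asserted {val!r}")
                            if msg not in store.conflicts:
                                store.conflicts.append(msg)
                                log.warning("%s", msg)
                    elif fld == "description":
                        if rec.description is None:
                            rec.description = val
        store.rebuild_index()
        cur = store.canonical_dump()
        if cur == prev:
            break
        prev = cur
    return store
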