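"""Identifier addition (fallback, policies, ortholog projection) and merges."""

import random
from collections import Counter

import pytest

from omixid.idmap import ColumnSpec, MatchPolicy, add_identifiers, integrate_tables, resolve_row
from omixid.tables import DataTable, TableError, read_table

from oracle_utils import brute_force_join, manifest_keyspace

SPECS2 = [ColumnSpec("SYM", "symbol"), ColumnSpec("ENS", "ensembl_gene")]


def _two_col_table(manifest, tax, n=30, corrupt_symbol=False):
    """Table with a symbol column and an Ensembl column for the same gene."""
    rows = []
    for g in manifest.genes:
        if g["tax_id"] != tax:
            continue
        sym = "ZZZNOPE" if corrupt_symbol else g["symbol"]
        rows.append([sym, g["ensembl_gene"]])
        if len(rows) == n:
            break
    return DataTable.from_rows(["SYM", "ENS"], rows)


def test_fallback_second_spec_used_when_first_fails(default_world):
    store = default_world.stores.xref
    g = default_world.manifest.genes[0]
    row = {"SYM": "not-a-symbol", "ENS": g["ensembl_gene"]}
    hits = resolve_row(store, row, SPECS2)
    assert [h.entrez_id for h in hits] == [g["entrez"]]


def test_fallback_is_not_a_union(default_world):
    # first spec resolves -> the second, pointing at a different gene, is ignored
    store = default_world.stores.xref
    g0, g1 = default_world.manifest.genes[0], default_world.manifest.genes[1]
    row = {"SYM": g0["symbol"], "ENS": g1["ensembl_gene"]}
    hits = resolve_row(store, row, SPECS2, in_tax=[g0["tax_id"]])
    assert [h.entrez_id for h in hits] == [g0["entrez"]]


def test_empty_cells_resolve_to_nothing(default_world):
    assert resolve_row(default_world.stores.xref, {"SYM": "", "ENS": " "}, SPECS2) == []


def test_out_tax_projects_through_orthologs(default_world):
    man, store = default_world.manifest, default_world.stores.xref
    edges = {}
    for a, ta, b, tb in man.ortholog_edges:
        edges.setdefault(a, set()).add(b)
    by_ens = {g["ensembl_gene"]: g for g in man.genes}
    gene = next(g for g in man.genes if g["tax_id"] == 9606
                and g["ensembl_gene"] in edges)
    row = {"ENS": gene["ensembl_gene"], "SYM": ""}
    hits = resolve_row(store, row, SPECS2, in_tax=[9606], out_tax=[7955])
    expected = sorted(by_ens[p]["entrez"] for p in edges[gene["ensembl_gene"]])
    assert sorted(h.entrez_id for h in hits) == expected
    # without an output restriction the direct hit is returned
    direct = resolve_row(store, row, SPECS2, in_tax=[9606])
    assert [h.entrez_id for h in direct] == [gene["entrez"]]


def test_add_identifiers_first_policy_matches_manifest(default_world):
    man, store = default_world.manifest, default_world.stores.xref
    table = _two_col_table(man, 9606)
    by_ens = {g["ensembl_gene"]: g for g in man.genes}
    out = add_identifiers(store, table, SPECS2, ["entrez", "symbol", "tax_id"],
                          in_tax=[9606])
    assert out.header == ("SYM", "ENS", "entrez", "symbol", "tax_id")
    for row in out.rows:
        g = by_ens[row[1]]
        assert row[2:] == (g["entrez"], g["symbol"], str(g["tax_id"]))


def test_policy_row_count_algebra(default_world):
    man, store = default_world.manifest, default_world.stores.xref
    table = _two_col_table(man, 9606, n=40)
    hits_per_row = [len(resolve_row(store, dict(zip(table.header, r)), SPECS2,
                                    out_tax=[7955])) for r in table.rows]
    for policy in (MatchPolicy.FIRST, MatchPolicy.JOIN_IN_ROW):
        out = add_identifiers(store, table, SPECS2, ["entrez"], out_tax=[7955],
                              policy=policy)
        assert out.n_rows == table.n_rows
    expanded = add_identifiers(store, table, SPECS2, ["entrez"], out_tax=[7955],
                               policy=MatchPolicy.EXPAND_ROWS)
    assert expanded.n_rows == sum(max(1, h) for h in hits_per_row)
    assert any(h > 1 for h in hits_per_row)  # one-to-many links exercised


def test_expand_rows_share_original_cells(default_world):
    man, store = default_world.manifest, default_world.stores.xref
    table = _two_col_table(man, 9606, n=40)
    out = add_identifiers(store, table, SPECS2, ["ensembl_gene"], out_tax=[7955],
                          policy=MatchPolicy.EXPAND_ROWS)
    originals = Counter(r[:2] for r in out.rows)
    assert set(originals) == set(table.rows)  # zero-hit rows retained too


def test_missing_spec_label_fatal_before_work(default_world):
    table = DataTable.from_rows(["X"], [["1"]])
    with pytest.raises(TableError, match="not in header"):
        add_identifiers(default_world.stores.xref, table,
                        [ColumnSpec("nope", "entrez")], ["symbol"])


def test_string_equality_self_merge_identity(default_world):
    table = read_table(next(p for n, p in default_world.user_files.items()
                            if n.startswith("genes_9606")))
    out = integrate_tables(None, table, table, [ColumnSpec("GeneID")],
                           [ColumnSpec("GeneID")], mode="string-equality",
                           intersection_only=True)
    # unique keys: every row matches exactly itself
    assert out.n_rows == table.n_rows
    for row in out.rows:
        assert row[:3] == row[3:]


def test_conversion_intersection_matches_manifest_count(default_world):
    man, store = default_world.manifest, default_world.stores.xref
    ta = read_table(default_world.user_files["genes_9606.txt"])
    tb = read_table(default_world.user_files["genes_7955.txt"])
    out = integrate_tables(store, ta, tb, [ColumnSpec("GeneID", "ensembl_gene")],
                           [ColumnSpec("GeneID", "ensembl_gene")],
                           mode="conversion", intersection_only=True)
    assert out.n_rows == man.data["expected_integration_pairs"]


@pytest.mark.parametrize("intersection", [True, False])
def test_conversion_merge_equals_manifest_oracle(default_world, intersection):
    """Hash-join implementation vs a nested-loop join whose keys come from
    the manifest alone."""
    man, store = default_world.manifest, default_world.stores.xref
    ta = read_table(default_world.user_files["genes_9606.txt"])
    tb = read_table(default_world.user_files["genes_7955.txt"])
    out = integrate_tables(store, ta, tb, [ColumnSpec("GeneID", "ensembl_gene")],
                           [ColumnSpec("GeneID", "ensembl_gene")],
                           mode="conversion", intersection_only=intersection)
    keyspace = manifest_keyspace(man)
    empty = frozenset()
    ka = [keyspace.get(r[0], empty) for r in ta.rows]
    kb = [keyspace.get(r[0], empty) for r in tb.rows]
    assert Counter(out.rows) == brute_force_join(ta.rows, tb.rows, ka, kb, intersection)


def test_merge_symmetry_in_intersection_mode(default_world):
    store = default_world.stores.xref
    ta = read_table(default_world.user_files["genes_9606.txt"])
    tb = read_table(default_world.user_files["genes_7955.txt"])
    spec = [ColumnSpec("GeneID", "ensembl_gene")]
    ab = integrate_tables(store, ta, tb, spec, spec, "conversion",
                          intersection_only=True)
    ba = integrate_tables(store, tb, ta, spec, spec, "conversion",
                          intersection_only=True)
    n = ta.n_cols
    assert Counter(ab.rows) == Counter(r[n:] + r[:n] for r in ba.rows)


def test_fallback_dominance_under_corruption(default_world):
    """Corrupting later key columns never changes rows resolvable earlier."""
    man, store = default_world.manifest, default_world.stores.xref
    table = _two_col_table(man, 9606, n=50)
    baseline = add_identifiers(store, table, SPECS2, ["entrez"])
    rng = random.Random(99)
    for _ in range(100):
        i = rng.randrange(table.n_rows)
        rows = list(table.rows)
        sym, _ens = rows[i]
        rows[i] = (sym, f"CORRUPT{rng.randrange(10 ** 6)}")
        out = add_identifiers(store, DataTable.from_rows(table.header, rows),
                              SPECS2, ["entrez"])
        assert out.rows[i][-1] == baseline.rows[i][-1]
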