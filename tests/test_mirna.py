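"""Name normalization, consensus target queries, reverse lookup, merging."""

import pytest

from omixid.idmap import ColumnSpec, MatchPolicy
from omixid.mirna import (
    TARGET_DBS, convert_mirna_column, merge_with_expression, normalize_mirna,
    query_targets, reverse_lookup,
)
from omixid.tables import DataTable, TableError, read_table

from oracle_utils import manifest_pairs_at_k


def _forward_pairs(world, k, dbs=TARGET_DBS, names=None):
    """(accession, gene entrez) pairs returned by the forward query."""
    st = world.stores
    if names is None:
        names = [m["current_name"] for m in world.manifest.mirnas]
    out = query_targets(st.targets, st.names, names, selected_dbs=dbs,
                        min_support=k, append_gene_ids=True, xref_store=st.xref)
    return {(r[2], r[6]) for r in out.rows if r[6]}


# -- normalization ----------------------------------------------------------


def test_alias_resolves_to_current_name(default_world):
    names = default_world.stores.names
    ambiguous = {a["alias"].casefold()
                 for a in default_world.manifest.data["ambiguous_aliases"]}
    checked = 0
    for m in default_world.manifest.mirnas:
        for alias in m["aliases"]:
            if alias.casefold() in ambiguous:
                continue
            res = normalize_mirna(names, alias)
            assert res.status == "alias"
            assert res.current_name == m["current_name"]
            assert res.mature_accession == m["mature_accession"]
            checked += 1
    assert checked > 0


def test_current_name_is_exact_and_idempotent(default_world):
    names = default_world.stores.names
    for m in default_world.manifest.mirnas[:10]:
        res = normalize_mirna(names, m["current_name"])
        assert res.status == "exact" and res.current_name == m["current_name"]
        again = normalize_mirna(names, res.current_name)
        assert again.current_name == res.current_name
        assert again.mature_accession == res.mature_accession


def test_matching_is_case_insensitive(default_world):
    names = default_world.stores.names
    m = default_world.manifest.mirnas[0]
    res = normalize_mirna(names, m["current_name"].upper())
    assert res.status == "exact" and res.current_name == m["current_name"]


def test_ambiguous_alias_reports_both_candidates(default_world):
    names = default_world.stores.names
    for amb in default_world.manifest.data["ambiguous_aliases"]:
        res = normalize_mirna(names, amb["alias"])
        assert res.status == "ambiguous"
        assert sorted(res.candidates) == sorted(amb["accessions"])
        assert res.current_name == ""  # never silently resolved


def test_species_restriction_filters_before_status(default_world):
    names = default_world.stores.names
    zeb = next(m for m in default_world.manifest.mirnas if m["tax_id"] == 7955)
    assert normalize_mirna(names, zeb["current_name"], [9606]).status == "unresolved"
    assert normalize_mirna(names, zeb["current_name"], [7955]).status == "exact"


# -- forward query ----------------------------------------------------------


def test_support_threshold_matches_manifest_vectors(default_world):
    man = default_world.manifest
    for k in (1, 2, 3, 4):
        assert _forward_pairs(default_world, k) == manifest_pairs_at_k(man, k)


def test_k1_union_k4_intersection_and_monotonicity(default_world):
    man = default_world.manifest
    union = {(p["mature_accession"], p["gene_entrez"]) for p in man.target_pairs}
    inter = {(p["mature_accession"], p["gene_entrez"]) for p in man.target_pairs
             if len(p["dbs"]) == 4}
    at = {k: _forward_pairs(default_world, k) for k in (1, 2, 3, 4)}
    assert at[1] == union
    assert at[4] == inter
    assert at[4] <= at[3] <= at[2] <= at[1]


def test_db_restriction_never_adds_pairs(default_world):
    man = default_world.manifest
    for dbs in (("microcosm",), ("targetscan", "mirtarbase"),
                ("microcosm", "microrna_org", "targetscan")):
        got = _forward_pairs(default_world, 1, dbs=dbs)
        assert got == manifest_pairs_at_k(man, 1, dbs)


def test_unresolved_name_yields_status_row(default_world):
    st = default_world.stores
    out = query_targets(st.targets, st.names, ["zzz-miR-0-0p"], min_support=1)
    assert out.n_rows == 1
    row = dict(zip(out.header, out.rows[0]))
    assert row["status"] == "unresolved" and row["gene_entrez"] == ""


def test_support_above_selection_is_fatal(default_world):
    st = default_world.stores
    with pytest.raises(TableError, match="min_support"):
        query_targets(st.targets, st.names, ["x"], selected_dbs=("microcosm",),
                      min_support=2)


def test_scores_reported_verbatim_per_database(default_world):
    man, st = default_world.manifest, default_world.stores
    pair = next(p for p in man.target_pairs if "microcosm" in p["dbs"])
    out = query_targets(st.targets, st.names, [pair["mirna_name"]], min_support=1,
                        append_gene_ids=True, xref_store=st.xref)
    row = next(dict(zip(out.header, r)) for r in out.rows
               if r[6] == pair["gene_entrez"])
    assert float(row["microcosm_score"]) == pair["dbs"]["microcosm"]
    assert "mirtarbase_score" not in out.header  # validated db has no score


# -- reverse query ----------------------------------------------------------


def test_reverse_applies_same_support_filter(default_world):
    man, st = default_world.stores.xref, default_world.stores
    by_gene = {}
    for p in default_world.manifest.target_pairs:
        by_gene.setdefault(p["gene_entrez"], []).append(p)
    gene, plist = next(
        (g, ps) for g, ps in by_gene.items()
        if any(len(p["dbs"]) >= 3 for p in ps) and any(len(p["dbs"]) == 1 for p in ps))
    table = DataTable.from_rows(["Entrez"], [[gene]])
    out = reverse_lookup(st.targets, st.names, table, [ColumnSpec("Entrez", "entrez")],
                         min_support=2, xref_store=st.xref)
    got = {r[-2] for r in out.rows if r[-2]}
    expected = {p["mature_accession"] for p in plist if len(p["dbs"]) >= 2}
    assert got == expected
    assert all(p["mature_accession"] not in got
               for p in plist if len(p["dbs"]) < 2)


@pytest.mark.parametrize("k", [1, 2, 3, 4])
def test_forward_reverse_symmetry_exhaustive(stress_world, k):
    man, st = stress_world.manifest, stress_world.stores
    forward = _forward_pairs(stress_world, k)
    genes = sorted({p["gene_entrez"] for p in man.target_pairs})
    table = DataTable.from_rows(["Entrez"], [[g] for g in genes])
    out = reverse_lookup(st.targets, st.names, table, [ColumnSpec("Entrez", "entrez")],
                         min_support=k, xref_store=st.xref)
    reverse = {(r[-2], r[0]) for r in out.rows if r[-2]}
    assert reverse == forward


def test_reverse_unresolvable_row_retained_blank(default_world):
    st = default_world.stores
    table = DataTable.from_rows(["Entrez"], [["999999999"]])
    out = reverse_lookup(st.targets, st.names, table, [ColumnSpec("Entrez", "entrez")])
    assert out.n_rows == 1 and out.rows[0] == ("999999999", "", "", "")


def test_reverse_policies(default_world):
    st = default_world.stores
    genes = sorted({p["gene_entrez"] for p in default_world.manifest.target_pairs})
    table = DataTable.from_rows(["Entrez"], [[g] for g in genes[:20]])
    spec = [ColumnSpec("Entrez", "entrez")]
    joined = reverse_lookup(st.targets, st.names, table, spec,
                            policy=MatchPolicy.JOIN_IN_ROW)
    assert joined.n_rows == table.n_rows
    first = reverse_lookup(st.targets, st.names, table, spec, policy=MatchPolicy.FIRST)
    assert first.n_rows == table.n_rows
    expanded = reverse_lookup(st.targets, st.names, table, spec)
    assert expanded.n_rows >= table.n_rows


# -- expression merge and column conversion ---------------------------------


def test_merge_with_expression_counts(default_world):
    st = default_world.stores
    names = [default_world.manifest.mirnas[0]["current_name"]]
    targets = query_targets(st.targets, st.names, names, min_support=1,
                            append_gene_ids=True, xref_store=st.xref)
    expr_path = default_world.user_files["genes_9606.txt"]
    expr = read_table(expr_path)
    ikeys = [ColumnSpec("gene_ensembl", "ensembl_gene"),
             ColumnSpec("gene_entrez", "entrez")]
    ekeys = [ColumnSpec("GeneID", "ensembl_gene")]
    merged = merge_with_expression(targets, expr, ikeys, ekeys, st.xref,
                                   intersection_only=True)
    # oracle: target genes whose ensembl id survives in the expression table
    meta = default_world.manifest.data["user_tables"]["genes_9606.txt"]["rows"]
    expr_ids = {m["gene_id"] for m in meta if not m["corrupted"]}
    expected = sum(1 for r in targets.rows if r[8] in expr_ids)
    assert merged.n_rows == expected
    outer = merge_with_expression(targets, expr, ikeys, ekeys, st.xref,
                                  intersection_only=False)
    assert outer.n_rows >= targets.n_rows  # all interaction rows preserved


def test_merge_with_empty_expression_table(default_world):
    st = default_world.stores
    names = [default_world.manifest.mirnas[0]["current_name"]]
    targets = query_targets(st.targets, st.names, names, min_support=1,
                            append_gene_ids=True, xref_store=st.xref)
    empty = DataTable.from_rows(["GeneID", "log2FC"], [])
    merged = merge_with_expression(targets, empty,
                                   [ColumnSpec("gene_ensembl", "ensembl_gene")],
                                   [ColumnSpec("GeneID", "ensembl_gene")],
                                   st.xref, intersection_only=True)
    assert merged.n_rows == 0


def test_convert_mirna_column_against_manifest(default_world):
    st = default_world.stores
    tax = default_world.spec.taxa[0]
    path = default_world.user_files[f"mirnas_{tax}.txt"]
    table = read_table(path)
    out = convert_mirna_column(st.names, table, "miRNA")
    assert out.header[-2:] == ("current_mirna_name", "mirna_status")
    meta = default_world.manifest.data["user_tables"][f"mirnas_{tax}.txt"]["rows"]
    for m, row in zip(meta, out.rows):
        assert row[-1] == m["expected_status"]
        assert row[-2] == m["expected_current"]
    # idempotence: converting already-current names appends the same column
    current = DataTable.from_rows(["miRNA"], [[r[-2]] for r in out.rows if r[-2]])
    again = convert_mirna_column(st.names, current, "miRNA")
    assert all(r[0] == r[1] for r in again.rows)
    assert all(r[2] == "exact" for r in again.rows)
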