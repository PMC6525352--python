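"""Independent oracles computed from the ground-truth manifest only.

Nothing here calls the store/lookup code under test: merge keys come
straight from the manifest's gene tuples and ortholog edge list, and support
counting reads the manifest's per-pair database-membership vectors.
"""

from collections import Counter


def manifest_keyspace(manifest):
    """cell value (an Ensembl gene ID) -> frozenset of canonical merge keys,
    built purely from the manifest: the gene's own Ensembl ID plus every
    ortholog partner reachable by one edge."""
    partners = {}
    for a, ta, b, tb in manifest.ortholog_edges:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    mapping = {}
    for g in manifest.genes:
        ens = g["ensembl_gene"]
        mapping[ens] = frozenset({ens} | partners.get(ens, set()))
    return mapping


def brute_force_join(rows_a, rows_b, keys_a, keys_b, intersection_only):
    """All-pairs nested-loop join.

    ``keys_a[i]`` / ``keys_b[j]`` are the per-row key sets; a pair matches
    when the sets intersect.  Returns the output row multiset (Counter of
    concatenated cell tuples), with unmatched rows padded by blanks unless
    ``intersection_only``.
    """
    out = Counter()
    width_a = len(rows_a[0]) if rows_a else 0
    width_b = len(rows_b[0]) if rows_b else 0
    b_matched = set()
    for i, ra in enumerate(rows_a):
        matched = False
        for j, rb in enumerate(rows_b):
            if keys_a[i] & keys_b[j]:
                out[tuple(ra) + tuple(rb)] += 1
                matched = True
                b_matched.add(j)
        if not matched and not intersection_only:
            out[tuple(ra) + ("",) * width_b] += 1
    if not intersection_only:
        for j, rb in enumerate(rows_b):
            if j not in b_matched:
                out[("",) * width_a + tuple(rb)] += 1
    return out


def manifest_pairs_at_k(manifest, k, selected_dbs=None):
    """{(mature accession, gene entrez)} with support >= k, from the
    manifest membership vectors alone."""
    pairs = set()
    for p in manifest.target_pairs:
        dbs = set(p["dbs"])
        if selected_dbs is not None:
            dbs &= set(selected_dbs)
        if len(dbs) >= k:
            pairs.add((p["mature_accession"], p["gene_entrez"]))
    return pairs
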