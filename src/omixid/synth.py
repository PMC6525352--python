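"""Deterministic synthetic reference bundles with ground-truth manifests.

Real cross-reference snapshots (NCBI Gene, Ensembl, UniProt, miRBase, the
four target databases) are large, versioned, and unavailable offline, so
every behavior in this package is exercised against *synthetic* bundles
generated here.  The generator emits every flat-file dialect the loaders
read, plus a ground-truth manifest written in the same pass from the same
random stream, so every expected value a test needs — which gene carries
which accessions, which ortholog edges exist, which (miRNA, gene) pair sits
in which databases, which user-table rows were deliberately corrupted — is
recomputable from the manifest alone, independent of the loaders under test.

Synthetic identifiers follow the real grammars (``ENSG``/``ENSDARG`` + 11
digits, ``MIMAT`` + 7 digits, ``hsa-miR-N-3p``) so format-handling code
paths are exercised.  One ``random.Random(seed)`` stream drives everything:
the same (seed, spec) always produces byte-identical bundles.

What this emulates and what it does not: identifier structure, ortholog
topology (including engineered one-to-many links), name-history chains with
engineered ambiguity, and per-database membership drawn independently per
pair (so support counts follow a Poisson-binomial law).  It makes no attempt
to mimic biological co-expression, realistic score distributions, or the
size of real releases.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from .refdata import BUNDLE_SCHEMA_VERSION

__all__ = ["FixtureSpec", "GroundTruthManifest", "gen_reference", "gen_user_tables", "PRESETS"]

# taxon -> (ensembl gene prefix, mirna prefix, symbols uppercase?)
_TAXON_STYLE = {
    9606: ("ENSG", "hsa", True),
    10090: ("ENSMUSG", "mmu", True),
    10116: ("ENSRNOG", "rno", True),
    7955: ("ENSDARG", "dre", False),
    9544: ("ENSMMUG", "mml", True),
}

# a few real-looking symbol stems so symbol-based paths look like field data;
# ortholog partners share the stem with species-conventional casing
_SYMBOL_STEMS = ["CYP1A", "CYP1B1", "AHR", "TP53", "GSTP1", "NQO1", "AHRR", "ARNT"]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic world; defaults are the standard test bundle.

    ``db_probs`` are the independent per-database inclusion probabilities of
    a candidate (miRNA, gene) pair, ordered (microcosm, microrna_org,
    targetscan, mirtarbase).
    """

    seed: int = 0
    taxa: tuple[int, ...] = (9606, 7955)
    n_genes_per_taxon: int = 100
    ortholog_fraction: float = 0.6
    one_to_many_fraction: float = 0.1
    n_mirnas_per_taxon: int = 30
    alias_max: int = 2
    n_ambiguous_aliases: int = 1
    n_symbol_conflicts: int = 1
    targets_per_mirna: int = 8
    db_probs: tuple[float, float, float, float] = (0.6, 0.5, 0.5, 0.3)
    typo_fraction: float = 0.1
    n_user_rows: Optional[int] = None  # default: one row per gene

    def __post_init__(self) -> None:
        for p in self.db_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"db_probs must lie in [0,1], got {self.db_probs}")
        if not 0.0 <= self.typo_fraction <= 1.0:
            raise ValueError("typo_fraction must lie in [0,1]")


PRESETS: dict[str, FixtureSpec] = {
    "default": FixtureSpec(),
    "two-species-small": FixtureSpec(n_genes_per_taxon=20, n_mirnas_per_taxon=8),
    "mirna-stress": FixtureSpec(
        n_genes_per_taxon=60, n_mirnas_per_taxon=40, targets_per_mirna=15,
        db_probs=(0.7, 0.6, 0.5, 0.4),
    ),
}


@dataclass
class GroundTruthManifest:
    """Everything the generator decided, for oracle tests.

    ``data`` holds plain-JSON structures: per-gene cross-reference tuples,
    the ortholog edge list, per-alias resolutions, per-pair database
    membership with scores, engineered conflicts/ambiguities, and (after
    :func:`gen_user_tables`) per-row expectations for the user tables.
    """

    data: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.data, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(data=json.loads(Path(path).read_text(encoding="utf-8")))

    # -- convenience views -------------------------------------------------

    @property
    def genes(self) -> list[dict]:
        return self.data["genes"]

    @property
    def ortholog_edges(self) -> list[list]:
        return self.data["ortholog_edges"]

    @property
    def mirnas(self) -> list[dict]:
        return self.data["mirnas"]

    @property
    def target_pairs(self) -> list[dict]:
        return self.data["target_pairs"]


def _taxon_style(tax: int) -> tuple[str, str, bool]:
    return _TAXON_STYLE.get(tax, (f"ENSX{tax % 97:02d}G", f"t{tax % 997}", True))


def gen_reference(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, GroundTruthManifest]:
    """Write a complete reference bundle and its ground-truth manifest.

    Emits ``genes.tsv``, ``gene2ensembl.tsv``, ``uniprot_map.tsv``,
    ``orthologs.tsv``, ``refseq.tsv``, the miRBase-style ``mirna_mature.tsv``
    and ``mirna_aliases.tsv``, one target TSV per database, a bundle
    ``manifest.json``, and ``ground_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    spec_dict = json.loads(json.dumps(asdict(spec)))  # tuples -> lists
    manifest = GroundTruthManifest({
        "spec": spec_dict, "genes": [], "ortholog_edges": [],
        "mirnas": [], "ambiguous_aliases": [], "symbol_conflicts": [],
        "target_pairs": [], "user_tables": {},
    })

    # ---- genes ----------------------------------------------------------
    entrez_counter = 1001
    ens_counter = 10_000_000_001
    uni_counter = 10001
    nm_counter = 500001
    genes_by_taxon: dict[int, list[dict]] = {}
    for t_idx, tax in enumerate(spec.taxa):
        prefix, _, upper = _taxon_style(tax)
        genes_by_taxon[tax] = []
        for j in range(spec.n_genes_per_taxon):
            if j < len(_SYMBOL_STEMS):
                stem = _SYMBOL_STEMS[j]
            else:
                stem = f"SYG{j:04d}"
            symbol = stem if upper else stem.lower()
            entrez = str(entrez_counter); entrez_counter += 1
            ensg = f"{prefix}{ens_counter:011d}"; ens_counter += 1
            enst = f"{prefix.replace('G', 'T', 1) if 'G' in prefix else prefix + 'T'}{ens_counter:011d}"
            ensp = f"{prefix.replace('G', 'P', 1) if 'G' in prefix else prefix + 'P'}{ens_counter:011d}"
            ens_counter += 1
            uniprot = f"Q{uni_counter:05d}"; uni_counter += 1
            refseq = f"NM_{nm_counter:06d}"; nm_counter += 1
            n_syn = rng.randint(0, 2)
            synonyms = [f"{symbol}-S{i + 1}" for i in range(n_syn)]
            gene = {
                "tax_id": tax, "entrez": entrez, "symbol": symbol,
                "synonyms": synonyms, "ensembl_gene": ensg,
                "ensembl_transcript": enst, "ensembl_protein": ensp,
                "uniprot": uniprot, "refseq": refseq,
                "description": f"synthetic gene {symbol} [taxon {tax}]",
            }
            genes_by_taxon[tax].append(gene)
            manifest.data["genes"].append(gene)

    # ---- ortholog edges between the first two taxa ----------------------
    edges: list[tuple[str, int, str, int]] = []
    if len(spec.taxa) >= 2:
        tax_a, tax_b = spec.taxa[0], spec.taxa[1]
        n_link = int(round(spec.ortholog_fraction * spec.n_genes_per_taxon))
        linked_idx = list(range(n_link))
        spare_b = list(range(n_link, spec.n_genes_per_taxon))
        n_extra = int(round(spec.one_to_many_fraction * n_link))
        extra_sources = rng.sample(linked_idx, min(n_extra, len(linked_idx)))
        for j in linked_idx:
            ga = genes_by_taxon[tax_a][j]["ensembl_gene"]
            gb = genes_by_taxon[tax_b][j]["ensembl_gene"]
            edges.append((ga, tax_a, gb, tax_b))
        for j in extra_sources:
            if not spare_b:
                break
            ga = genes_by_taxon[tax_a][j]["ensembl_gene"]
            gb = genes_by_taxon[tax_b][spare_b.pop(0)]["ensembl_gene"]
            edges.append((ga, tax_a, gb, tax_b))
        manifest.data["ortholog_edges"] = [list(e) for e in edges]

    # ---- engineered symbol conflicts ------------------------------------
    conflict_genes = []
    all_genes = manifest.data["genes"]
    for i in range(min(spec.n_symbol_conflicts, len(all_genes))):
        g = all_genes[(i * 7) % len(all_genes)]
        conflict_genes.append(g)
        manifest.data["symbol_conflicts"].append({
            "tax_id": g["tax_id"], "entrez": g["entrez"],
            "kept_symbol": g["symbol"], "conflicting": g["symbol"] + "-ALT",
        })

    # ---- write gene-side bundle files ------------------------------------
    def w(path: Path, header: list[str], rows: list[list[str]]) -> int:
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(header) + "\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")
        return len(rows)

    counts: dict[str, int] = {}
    counts["genes.tsv"] = w(out / "genes.tsv",
        ["tax_id", "entrez_id", "symbol", "synonyms", "description"],
        [[str(g["tax_id"]), g["entrez"], g["symbol"],
          "|".join(g["synonyms"]) or "-", g["description"]]
         for g in all_genes])
    counts["gene2ensembl.tsv"] = w(out / "gene2ensembl.tsv",
        ["tax_id", "entrez_id", "ensembl_gene", "ensembl_transcript", "ensembl_protein"],
        [[str(g["tax_id"]), g["entrez"], g["ensembl_gene"],
          g["ensembl_transcript"], g["ensembl_protein"]]
         for g in all_genes])
    uni_rows: list[list[str]] = []
    conflict_set = {(c["tax_id"], c["entrez"]) for c in manifest.data["symbol_conflicts"]}
    for g in all_genes:
        uni_rows.append([g["uniprot"], "entrez", g["entrez"], str(g["tax_id"])])
        uni_rows.append([g["uniprot"], "ensembl_gene", g["ensembl_gene"], str(g["tax_id"])])
        if (g["tax_id"], g["entrez"]) in conflict_set:
            uni_rows.append([g["uniprot"], "symbol", g["symbol"] + "-ALT", str(g["tax_id"])])
    counts["uniprot_map.tsv"] = w(out / "uniprot_map.tsv",
        ["uniprot_acc", "id_type", "value", "tax_id"], uni_rows)
    counts["orthologs.tsv"] = w(out / "orthologs.tsv",
        ["gene_a", "tax_a", "gene_b", "tax_b"],
        [[a, str(ta), b, str(tb)] for a, ta, b, tb in edges])
    counts["refseq.tsv"] = w(out / "refseq.tsv",
        ["tax_id", "entrez_id", "refseq_acc"],
        [[str(g["tax_id"]), g["entrez"], g["refseq"]] for g in all_genes])

    # ---- miRNAs ----------------------------------------------------------
    mimat_counter = 1_000_001
    mi_counter = 100_001
    for tax in spec.taxa:
        _, mir_prefix, _ = _taxon_style(tax)
        for j in range(spec.n_mirnas_per_taxon):
            num = 100 + j
            arm = "5p" if j % 2 else "3p"
            current = f"{mir_prefix}-miR-{num}-{arm}"
            acc = f"MIMAT{mimat_counter:07d}"; mimat_counter += 1
            stem_acc = f"MI{mi_counter:07d}"; mi_counter += 1
            seq = "".join(rng.choice("ACGU") for _ in range(22))
            n_alias = rng.randint(0, spec.alias_max)
            aliases = []
            if n_alias >= 1:
                aliases.append(f"{mir_prefix}-miR-{num}")
            if n_alias >= 2:
                aliases.append(f"{mir_prefix}-mir-{num}-prev")
            manifest.data["mirnas"].append({
                "current_name": current, "mature_accession": acc,
                "stemloop_accession": stem_acc, "tax_id": tax,
                "sequence": seq, "aliases": aliases,
            })
    # engineered ambiguous aliases: one historic name shared by two records
    mirnas = manifest.data["mirnas"]
    for i in range(spec.n_ambiguous_aliases):
        if len(mirnas) < 2:
            break
        m1, m2 = mirnas[2 * i % len(mirnas)], mirnas[(2 * i + 1) % len(mirnas)]
        if m1 is m2:
            break
        alias = f"shared-miR-amb{i}"
        m1["aliases"] = m1["aliases"] + [alias]
        m2["aliases"] = m2["aliases"] + [alias]
        manifest.data["ambiguous_aliases"].append({
            "alias": alias,
            "accessions": [m1["mature_accession"], m2["mature_accession"]],
        })
    counts["mirna_mature.tsv"] = w(out / "mirna_mature.tsv",
        ["name", "accession", "stemloop_accession", "tax_id", "sequence"],
        [[m["current_name"], m["mature_accession"], m["stemloop_accession"],
          str(m["tax_id"]), m["sequence"]] for m in mirnas])
    counts["mirna_aliases.tsv"] = w(out / "mirna_aliases.tsv",
        ["accession", "aliases"],
        [[m["mature_accession"], ";".join(m["aliases"])]
         for m in mirnas if m["aliases"]])

    # ---- target databases ------------------------------------------------
    from .mirna import TARGET_DBS  # canonical db order matches db_probs

    db_rows: dict[str, list[list[str]]] = {db: [] for db in TARGET_DBS}
    for m in mirnas:
        tax = m["tax_id"]
        pool = genes_by_taxon[tax]
        k = min(spec.targets_per_mirna, len(pool))
        for g in rng.sample(pool, k):
            membership: dict[str, Optional[float]] = {}
            for db, p in zip(TARGET_DBS, spec.db_probs):
                if rng.random() < p:
                    if db == "mirtarbase":
                        membership[db] = None
                    elif db == "microcosm":
                        membership[db] = round(rng.uniform(10.0, 22.0), 3)
                    elif db == "microrna_org":
                        membership[db] = round(-rng.uniform(0.1, 1.5), 4)
                    else:  # targetscan context-style score
                        membership[db] = round(-rng.uniform(0.01, 0.6), 3)
            if not membership:
                continue
            manifest.data["target_pairs"].append({
                "mature_accession": m["mature_accession"],
                "mirna_name": m["current_name"], "tax_id": tax,
                "gene_entrez": g["entrez"], "gene_symbol": g["symbol"],
                "gene_ensembl": g["ensembl_gene"],
                "dbs": {db: membership[db] for db in membership},
            })
            # per-db identifier habits: each db reports a different subset of
            # gene keys, forcing cross-db identity through the xref store
            name_cell = (m["current_name"] if rng.random() < 0.7
                         else m["mature_accession"])
            for db, score in membership.items():
                s = "-" if score is None else format(score, "g")
                if db == "microcosm":
                    row = [name_cell, str(tax), "-", "-", g["ensembl_gene"], s]
                elif db == "microrna_org":
                    row = [name_cell, str(tax), g["entrez"], g["symbol"], "-", s]
                elif db == "targetscan":
                    row = [name_cell, str(tax), "-", g["symbol"], g["ensembl_gene"], s]
                else:  # mirtarbase
                    row = [name_cell, str(tax), g["entrez"], g["symbol"], "-", "-"]
                db_rows[db].append(row)
    for db in TARGET_DBS:
        counts[f"targets_{db}.tsv"] = w(out / f"targets_{db}.tsv",
            ["mature_name_or_accession", "tax_id", "entrez", "symbol",
             "ensembl_gene", "score"], db_rows[db])

    bundle_manifest = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "source": "synthetic",
        "release": f"seed-{spec.seed}",
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(bundle_manifest, indent=1, sort_keys=True), encoding="utf-8")
    manifest.data["bundle_manifest"] = bundle_manifest
    manifest.save(out / "ground_truth.json")
    return out, manifest


def gen_user_tables(
    spec: FixtureSpec,
    manifest: GroundTruthManifest,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit per-taxon user tables emulating differential-expression output.

    Gene tables carry one Ensembl-gene ID column plus synthetic log2
    fold-change and q-value columns; miRNA tables mix current names, aliases
    and a ``typo_fraction`` of unresolvable names.  Which rows were corrupted
    (and hence every expected resolution / merge count) is recorded in the
    manifest, keyed by file name.  Uses a random stream derived from the
    spec seed, independent of bundle generation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed + 7_777_777)
    files: dict[str, Path] = {}
    genes_by_taxon: dict[int, list[dict]] = {}
    for g in manifest.genes:
        genes_by_taxon.setdefault(g["tax_id"], []).append(g)

    corrupted_gene_ids: dict[int, set[str]] = {}
    for tax in spec.taxa:
        pool = genes_by_taxon.get(tax, [])
        n_rows = spec.n_user_rows if spec.n_user_rows is not None else len(pool)
        if n_rows <= len(pool):
            chosen = pool[:n_rows]
        else:
            chosen = pool + [rng.choice(pool) for _ in range(n_rows - len(pool))]
        n_typo = int(round(spec.typo_fraction * len(chosen)))
        typo_rows = set(rng.sample(range(len(chosen)), n_typo)) if n_typo else set()
        rows = []
        row_meta = []
        corrupted_gene_ids[tax] = set()
        for i, g in enumerate(chosen):
            if i in typo_rows:
                gene_id = f"BADID{rng.randint(0, 10**9):09d}"
                corrupted_gene_ids[tax].add(g["ensembl_gene"])
            else:
                gene_id = g["ensembl_gene"]
            rows.append([gene_id, f"{rng.gauss(0.0, 2.0):.4f}",
                         f"{rng.uniform(0.0, 0.05):.3e}"])
            row_meta.append({"row": i, "gene_id": gene_id,
                             "true_ensembl": g["ensembl_gene"],
                             "corrupted": i in typo_rows})
        name = f"genes_{tax}.txt"
        path = out / name
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("GeneID\tlog2FC\tqvalue\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")
        files[name] = path
        manifest.data["user_tables"][name] = {
            "tax_id": tax, "id_column": "GeneID", "id_type": "ensembl_gene",
            "n_rows": len(rows), "corrupted_rows": sorted(typo_rows),
            "n_resolvable": len(rows) - len(typo_rows), "rows": row_meta,
        }

    # expected conversion-mode intersection between the first two taxa:
    # one (a,b) output pair per ortholog edge whose endpoint rows both
    # survived corruption and appear in the tables
    if len(spec.taxa) >= 2:
        tax_a, tax_b = spec.taxa[0], spec.taxa[1]
        ids_a = {m["true_ensembl"] for m in
                 manifest.data["user_tables"][f"genes_{tax_a}.txt"]["rows"]
                 if not m["corrupted"]}
        ids_b = {m["true_ensembl"] for m in
                 manifest.data["user_tables"][f"genes_{tax_b}.txt"]["rows"]
                 if not m["corrupted"]}
        n_pairs = sum(1 for a, ta, b, tb in manifest.ortholog_edges
                      if a in ids_a and b in ids_b)
        manifest.data["expected_integration_pairs"] = n_pairs

    # miRNA name tables
    mirnas_by_taxon: dict[int, list[dict]] = {}
    for m in manifest.mirnas:
        mirnas_by_taxon.setdefault(m["tax_id"], []).append(m)
    ambiguous = {a["alias"].casefold() for a in manifest.data["ambiguous_aliases"]}
    for tax in spec.taxa:
        pool = mirnas_by_taxon.get(tax, [])
        if not pool:
            continue
        n_typo = int(round(spec.typo_fraction * len(pool)))
        typo_rows = set(rng.sample(range(len(pool)), n_typo)) if n_typo else set()
        rows = []
        meta = []
        for i, m in enumerate(pool):
            usable_aliases = [a for a in m["aliases"] if a.casefold() not in ambiguous]
            if i in typo_rows:
                cell = f"xxx-miR-{rng.randint(100000, 999999)}"
                expect = "unresolved"
            elif usable_aliases and rng.random() < 0.4:
                cell = rng.choice(usable_aliases)
                expect = "alias"
            else:
                cell = m["current_name"]
                expect = "exact"
            rows.append([cell, f"{rng.gauss(0.0, 1.5):.4f}",
                         f"{rng.uniform(0.0, 0.05):.3e}"])
            meta.append({"row": i, "input_name": cell, "expected_status": expect,
                         "expected_current": "" if expect == "unresolved"
                         else m["current_name"],
                         "mature_accession": "" if expect == "unresolved"
                         else m["mature_accession"]})
        name = f"mirnas_{tax}.txt"
        path = out / name
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("miRNA\tlog2FC\tqvalue\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")
        files[name] = path
        manifest.data["user_tables"][name] = {
            "tax_id": tax, "id_column": "miRNA", "n_rows": len(rows),
            "corrupted_rows": sorted(typo_rows),
            "n_resolvable": len(rows) - len(typo_rows), "rows": meta,
        }
    return files
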