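"""Generate a synthetic reference bundle and inspect what it contains.

A bundle is a directory of flat-file tables (genes, Ensembl cross-refs,
UniProt maps, ortholog links, miRNA names and four target databases) plus a
ground-truth manifest recording every fact the generator invented — the
oracle every other example checks against.
"""

import tempfile
from pathlib import Path

from omixid import FixtureSpec, gen_reference, gen_user_tables, load_bundle_stores

root = Path(tempfile.mkdtemp(prefix="omixid_demo_"))
spec = FixtureSpec(seed=42, n_genes_per_taxon=50, n_mirnas_per_taxon=10)
bundle, manifest = gen_reference(spec, root)
files = gen_user_tables(spec, manifest, root / "user")

print(f"bundle written to {bundle}")
for p in sorted(bundle.iterdir()):
    print(f"  {p.name}")
stores = load_bundle_stores(bundle)
print(f"{len(stores.xref.records)} gene records across taxa "
      f"{sorted({r.tax_id for r in stores.xref.records})}")
print(f"{len(stores.names.records)} mature miRNAs, "
      f"{len(manifest.target_pairs)} (miRNA, gene) interactions")
# 50 genes per taxon for two taxa -> 100 records; interactions are drawn
# per database with the spec's inclusion probabilities.
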