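"""Normalize a column of miRNA names to their current miRBase-style names.

Metadata from older platforms often carries historical miRNA names; this
appends each row's current name as the final column plus an explicit status
(exact / alias / ambiguous / unresolved) — an ambiguous historical name is
reported, never silently resolved to one candidate.
"""

import tempfile
from pathlib import Path

from omixid import (
    DataTable, FixtureSpec, convert_mirna_column, gen_reference, load_bundle_stores,
)

root = Path(tempfile.mkdtemp(prefix="omixid_demo_"))
spec = FixtureSpec(seed=42, n_genes_per_taxon=20, n_mirnas_per_taxon=10)
bundle, manifest = gen_reference(spec, root)
stores = load_bundle_stores(bundle)

amb_names = {a["alias"] for a in manifest.data["ambiguous_aliases"]}
rows = []
for m in manifest.mirnas[:4]:
    rows.append([m["current_name"]])          # already current -> exact
    clean = [a for a in m["aliases"] if a not in amb_names]
    if clean:
        rows.append([clean[0]])               # historical -> alias
rows.append(["hsa-miR-999999"])               # unknown -> unresolved
amb = manifest.data["ambiguous_aliases"][0]["alias"]
rows.append([amb])                            # shared history -> ambiguous

table = DataTable.from_rows(["probe_mirna"], rows)
out = convert_mirna_column(stores.names, table, "probe_mirna")
print("\t".join(out.header))
for row in out.rows:
    print("\t".join(row))
# The input column is untouched; the appended current name is blank exactly
# when the status is unresolved or ambiguous.
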