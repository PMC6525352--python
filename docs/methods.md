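# Methods

This note records the semantics, numerical/tie-break choices and known
limitations of the `omixid` workflows, in the order a request flows through
them.

## User tables

User data is a headered tab-separated `.txt` file, UTF-8, tab the only
separator, no quoting; `\n` and `\r\n` are both accepted on read and `\n`
written.  Cells are opaque strings — no type inference, no numeric
reinterpretation — and every workflow preserves the original columns
leftmost, in order, byte-for-byte.  Rules the file format itself does not
fix are documented choices: duplicate header labels are deduplicated by
suffixing `.1`, `.2`, …; rows shorter than the header are padded with empty
cells; a row longer than the header is fatal (dropping user cells would
violate content preservation); an embedded tab is unrepresentable and fatal
on write; the empty string is the universal missing-value representation in
outputs.  A zero-hit row is retained with blank appended cells, never
deleted.

## Cross-reference store

Reference data is a *bundle*: a directory of headered TSVs (gene records,
Ensembl cross-references, UniProt maps, Ensembl-pivot ortholog pairs,
RefSeq) with a manifest carrying a schema version (mixing schema versions is
refused) and a release label that every run report echoes, because any count
is an artifact of a snapshot.  `-` and the empty string both mean absent,
following NCBI `gene_info` convention.  Loading is resource-faithful: each
resource contributes its own facts, and cross-resource assertions are held
as pending links that `backfill` applies — filling absent fields only, never
overwriting, iterating to a fixpoint (a UniProt link anchored on an Ensembl
gene can only land after an Ensembl link supplies that gene).  Conflicting
scalar assertions (two resources naming different symbols) keep the
higher-priority resource (NCBI > Ensembl > UniProt, the order the sources
are maintained in) and log the conflict.  The default loader runs backfill
immediately.

Matching rules: symbols and synonyms are compared case-insensitively
(human `TP53` vs zebrafish `tp53` conventions differ only in case);
accession-like IDs (ENSG…, NM\_…, UniProt) are compared case-sensitively
after whitespace trimming, since accessions have defined case.  All "ordered
list" results use one canonical record ordering: ascending taxon, then
ascending numeric Entrez ID; records lacking Entrez sort after, by their
lexicographically first Ensembl gene.  A "first result" policy needs a
deterministic definition, and this is it.

Ortholog links are stored symmetrically; a same-taxon request returns the
input unchanged.  All links are exposed unfiltered and multiple partners are
returned in lexicographic order — no confidence scoring is attempted.

## Identifier resolution and policies

Up to three identifier columns form a fallback chain: specs are tried left
to right and the first whose cell is non-empty *and* resolves (after the
input-species filter) fixes the hit set.  Fallback, not union — taking the
union across columns would inflate hits unpredictably when columns disagree.
Output-species handling: with no output restriction the direct hits are
returned; under an explicit restriction, hits outside it are projected
through ortholog links into the requested taxa.  Multiple-hit policies:
FIRST (default) keeps the canonical-first record; JOIN_IN_ROW pipe-joins
distinct values (`|`, the NCBI synonym-list delimiter) preserving row count;
EXPAND_ROWS emits one row per hit, so the output row count is
Σ max(1, hits(row)).

## Table integration

String-equality mode matches any key cell of one row against any key cell
of the other after trimming (case-folded when the column is declared a
symbol column; exact otherwise).  Conversion mode projects each row into a
canonical keyspace of Ensembl gene IDs — the resolved records' own Ensembl
genes plus their one-hop ortholog partners — and matches on non-empty
intersection; Ensembl is the pivot because it is the one namespace with
cross-species links.  Many-to-many matches emit every (a, b) pair
(lossless; downstream tools can deduplicate), and unmatched rows from either
side are retained with the other side blank unless the intersection is
requested.  The production implementation is an inverted-index hash join;
the test suite holds it equal, as row multisets, to an all-pairs nested-loop
join whose keys are computed from the generator manifest alone.

## miRNA name normalization

Names are matched case-insensitively; an exact current-name match wins over
an alias match; the species restriction filters candidates *before* status
assignment.  Status is one of exact / alias / ambiguous / unresolved; an
alias recorded under two accessions reports both candidates and resolves to
neither.  Arm suffixes (`-3p`/`-5p`) are never guessed: a bare historical
name resolves only through an explicit alias entry, because silent arm
inference manufactures false targets.

## Target consensus

Interactions are (mature accession, gene, database) triples; the three
predictive databases carry verbatim per-database scores (never combined into
a composite) and the validated database contributes support without a
score.  Duplicate (miRNA, gene) rows within one database — e.g.
per-transcript entries — collapse to one, keeping the largest-magnitude
score.  Cross-database gene identity: two rows denote the same gene when
their resolved Entrez IDs agree; rows lacking Entrez are resolved through
the cross-reference store first, then fall back to Ensembl gene, then
symbol, and rows that still share no key count as distinct.  Support of a
pair is the number of *selected* databases asserting it; the filter keeps
support ≥ k, with 1 ≤ k ≤ n selected enforced, default k = 1.  The same
selection and filter apply to the reverse (gene → miRNA) direction, whose
default policy is row expansion; forward and reverse are exact mirrors and
the suite checks the equivalence exhaustively.  Unresolved query names
produce a status row with blank targets rather than disappearing.

## Workflows, config, atomicity

Configs are validated before any file is read; unknown parameter or config
keys are fatal.  Outputs are written to a temporary file and renamed, so an
interrupted run never leaves a partial output at the target path.  Each run
writes `<output>.report.tsv` with rows in/out, resolved/unresolved counts, a
support histogram for miRNA queries, and the bundle release label.  Exit
codes: 0 success, 2 validation error, 1 runtime error.  The CLI takes flags
per subcommand or a single YAML config via `omixid run`.

## Synthetic bundles

The generator builds a two-species world (human 9606 / zebrafish 7955 by
default, 100 genes and 30 miRNAs per taxon) from one `random.Random(seed)`
stream, so the same (seed, spec) is byte-identical; Python's generator is
stable across platforms for the draws used, making manifests portable.
Identifiers follow real grammars (ENSG/ENSDARG + 11 digits, MIMAT + 7
digits, `hsa-miR-N-3p`).  Structural knobs and their defaults: 60% of genes
get a 1:1 ortholog partner and 10% of those an extra partner (one-to-many);
per-database membership of each candidate (miRNA, gene) pair is drawn
independently with probabilities (0.6, 0.5, 0.5, 0.3) so support counts
follow a Poisson-binomial law; alias chains of length 0–2 per miRNA with one
engineered ambiguous alias; one engineered cross-resource symbol conflict;
10% of user-table IDs corrupted (rows recorded).  User tables emulate
differential-expression output: one ID column plus log2 fold-change
(Gaussian, σ = 2) and q-value (uniform below 0.05) columns.  The generator
makes no attempt to mimic biological co-expression, realistic score
distributions, or release-scale data — passing tests demonstrate the
correctness of the plumbing and the consensus/merge logic, not performance
or recall on real snapshots.

Problem sizes used by the test suite and the acceptance run: bundles of
20–1000 genes per taxon, join-oracle checks on twenty fixtures up to
1000×1000 rows, a 40-miRNA / 15-targets-per-miRNA stress world for symmetry
checks, and a 500-row / 20%-corruption world for resolution-count recovery.
These sizes exercise every code path while keeping the whole suite a
few-second run.

## Known limitations

Historical counts published for comparable web-tool analyses (tens of
thousands of interactions for dozens of miRNAs, 37-row cross-species
intersections, and similar) depend on the specific reference snapshots those
services held and cannot be reproduced from synthetic bundles; this package
therefore treats such numbers as documented snapshot behavior, not as
targets.  No fuzzy or edit-distance ID matching; no probabilistic
disambiguation; no de-novo target prediction (no seed-match scanning or
free-energy scoring); no paralog or homology-confidence scoring; no live
database queries at lookup time (builders for real bundles are a documented
loader interface only); no Excel/CSV input and no gzip in this version.
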