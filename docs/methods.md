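# Methods

This note records how molscreen's methods are defined, which knobs matter,
and where the design was genuinely open.

## Molecular model and parsing

Molecules are RDKit `Mol` objects; a single aromaticity model (RDKit's
default perception) is applied uniformly at parse time and recorded in
project metadata, so re-parsing the same input always yields an identical
graph. Charged and isotopic species are accepted; stereochemistry is parsed
and preserved in the stored source string but ignored by every score in the
package (descriptors, fingerprints, MCS), which operate on the constitution
only. SDF input is restricted to V2000 connection tables — V3000 records
are rejected with an explicit error rather than silently mis-read. Unnamed
compounds are auto-named `CMPD<n>` by 1-based position in their set.

## Descriptors

* **MW** — sum of average (IUPAC) atomic masses over all atoms including
  hydrogens; reported to 2 decimals, full precision internally.
* **logP** — Crippen typed-atom contribution sum. The contribution table is
  the toolkit's packaged, versioned one (version recorded in
  `CONTRIBUTION_TABLE_VERSION`); cross-estimator agreement is explicitly
  not promised, only determinism and fragment additivity.
* **HBD / HBA** — the Lipinski counting convention: HBD is the number of
  O–H and N–H hydrogens, HBA the number of N and O atoms. This is the
  simplest defensible reading of the rule-of-five inputs; it is *not*
  acceptor perception, and HBA ≥ HBD is not guaranteed by construction.
* **TPSA** — Ertl fragment contributions over polar N/O fragments (Å²).
* **Rotatable bonds** — acyclic, single, non-aromatic bonds whose both
  endpoints have ≥ 2 heavy-atom neighbours; amide C–N bonds are excluded by
  default (toggle `count_amide_bonds=True`). This stated definition is
  implemented directly rather than through any toolkit's preset pattern, so
  the count matches the definition exactly (e.g. an ester C–O bond counts).
* **Rings** — SSSR count (cyclomatic number on connected graphs).

All extensive descriptors (MW, logP, TPSA, the counts) are additive over
disconnected fragments; the test-suite asserts this and recomputes every
count with an independent pure-Python graph walk.

## Likeness rules

Rule sets are data, not code: `data/rulesets.yaml` ships rule-of-five
(max_violations 1, after the original "fails if more than one" criterion),
lead-like and rule-of-three sets with the community-standard bounds. The
literature varies on exact lead-like thresholds, so the file is the single
source of truth and users can point the loader at their own. Boundary
equality passes for `le`/`ge` comparators (500.0 satisfies mw ≤ 500).

## PAINS screening

The packaged `data/pains.smt` is the public sln→SMARTS translation of the
interference filters (480 patterns, source families A/B/C merged into one
file; family kept as a third column). The translation is known to be
imperfect relative to the original sln rules, and SMARTS engines disagree
slightly on such patterns — this is why the screening layer exposes
`concordance_report`, which reduces any two runs over the same library to
(matching, only-A, only-B) counts. The original sln engine is not
re-implemented.

Matching details: patterns are compiled with explicit-hydrogen merging (the
published SMARTS carry `[#1]` atoms that must become H-count constraints);
one compound is flagged once regardless of how many filters hit; only the
first embedding per filter is recorded by default (`all_embeddings=True`
enumerates all, at cost). The test-suite verifies, pattern for pattern,
that the flagged sets agree with an independently maintained matcher over
the same merged filter set. An alternative MCS-based criterion
(`mcs_similarity_flag` against exemplar scaffolds) is exposed separately;
the two criteria are deliberately not combined into any composite score.

## Fingerprints and similarity

The path fingerprint enumerates every simple path of 0..7 bonds, writes it
as an atom/bond token string (aromatic atoms lower-case, bonds `-=#:`),
canonicalises direction by taking the lexicographically smaller of the two
readings, and sets bit `crc32(path) mod nbits` (default 1024). One bit per
distinct path string; CRC-32 is stable across platforms and Python
versions, so fingerprints are process-independent (tag
`simple-path/crc32/v1`). Defaults (1024 bits, depth 7) mirror the published
defaults of hashed path fingerprints generally; bit-exact compatibility
with any particular toolkit is a non-goal. Two all-zero fingerprints (both
empty graphs) are defined as similarity 1.0 and logged as degenerate.

The MCS search is an exhaustive branch-and-bound over connected partial
atom mappings: atoms match on element; aromatic bonds match only aromatic
bonds, non-aromatic bonds match on exact order. Connected (not
disconnected) MCS with an atom-count objective was chosen because it is the
common default of MCS similarity tools. Determinism: seed pairs and
extensions are explored in index order and only strictly larger subgraphs
replace the incumbent, so ties break deterministically; a seed-index
restriction and a visited-state memo prune symmetric duplicates. The
wall-clock `timeout` (default 10 s) truncates the search with
`exhausted=False`; callers (e.g. the MCS interference flag) treat a
truncated "below threshold" as *undetermined*, never as a negative. For
molecules up to ~30 heavy atoms the search completes well inside the
default timeout.

`search_library` with the MCS metric pre-screens candidates by fingerprint
Tanimoto at `threshold − 0.2`: the fingerprint score is only a heuristic
(not admissible) bound on the MCS score, so the margin is configurable and
the default errs generous.

## Clustering

MaxMin: first pick is the given seed index, or drawn from the RNG seed, or
index 0 when neither is supplied (so default runs are reproducible); each
later pick maximises the minimum Tanimoto distance to the picked set, ties
to the lowest index. The sequence of pick radii is non-increasing — a
property test, not an assumption.

k-means uses real-valued centroids (component-wise means of member bit
vectors) and the continuous Tanimoto similarity, which coincides with the
binary coefficient on 0/1 vectors; medoid variants were rejected as
needlessly restrictive. Because the mean-update step is not guaranteed to
decrease a Tanimoto objective the way it does a Euclidean one, an iteration
that would increase the objective is rolled back and the run stops; the
recorded objective history is therefore non-increasing by construction.
Empty clusters are reseeded with the point farthest from its own centroid,
and every cluster is non-empty on output. Defaults: `max_iter` 100, `tol`
1e-6. `cluster_set` wires the pipeline with the MaxMin picks as the k-means
initialisation and annotates records with cluster index and representative
flag; the MaxMin pick count equals k by construction.

## PubChem client

All network I/O in the package lives in one module behind an injectable
transport callable, so the whole suite runs with networking disabled and a
mock is a three-line function. The wire contract is the current PUG REST
gateway (identity lookup by standard InChIKey — a connectivity-only option
uses the key's skeleton block — and 2D similarity search with a percentage
threshold). Requests are rate-limited to 5/s per the public service's usage
policy and retried with jittered exponential backoff; offline mode raises
immediately with a typed error. HTTP 404 from the gateway means "no hits",
not failure.

## Reports and persistence

Column order is fixed: id, name, SMILES, the ten descriptors, one column
per likeness rule set, the PAINS flag, then annotation columns in
registration order. Filenames embed the zero-padded set number
(`set07.html`) — cosmetic, but stable for scripting. CSV is RFC-4180
(csv module); HTML is a single self-contained file with real hyperlinks for
url/file annotations; the PDF writer is a minimal dependency-free table
renderer (monospaced text, no structure depictions). Projects persist as a
versioned JSON document; loading a future version fails naming both
versions, and graph equality after a round trip is judged by canonical
SMILES.

## Synthetic fixtures — what they do and do not show

`make_fixture_set` produces three deterministic families: the alkane
homologous series (monotone descriptor ladder), twelve literature
interference exemplars (each verified to match ≥ 1 catalogue filter), and
`mixed_bench`, which interleaves the exemplars with ten approved-drug
structures verified to match none, at a recorded ratio (default roughly
1:1, shuffled by the RNG seed). The benchmark set is small (19 compounds)
and its classes are unambiguous by construction; passing it shows the
screening machinery is correct and engine-concordant, not that the filters'
false-positive/negative rates on a real vendor library are small — pattern
imperfection against the original sln rules is a property of the public
translation itself. Problem sizes used by the tests and the acceptance
script (≤ 19 compounds, MCS pairs ≤ 12 heavy atoms, clustering n ≤ 16)
were chosen as the smallest sets that exercise every code path and
discriminate the properties being tested.

## Known limitations

* logP values are estimator-specific; only additivity and determinism are
  contracted.
* SMARTS semantics differ subtly between engines; perfect agreement with
  the original sln rules is explicitly out of reach of the translated
  catalogue.
* The MCS search is exponential in the worst case; beyond ~30 heavy atoms
  rely on the timeout/`exhausted` contract.
* No 3D descriptors, stereo-aware scoring, Morgan/ECFP fingerprints, or
  hierarchical clustering.
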