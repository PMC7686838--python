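# Methods

## The procedure

scaffquery implements a ligand-based drug-repurposing loop. For a
disease (or a user-supplied protein list) it collects two kinds of
ligand evidence per target: compounds co-resolved in PDB structures, and
bioactivity measurements from ChEMBL-, PubChem- and IUPHAR-shaped
sources. After curation and activity labeling, the Bemis–Murcko
scaffolds of the active ligands are clustered by structural similarity,
each cluster is collapsed into one SMARTS substructure query, and those
queries are used to filter external drug libraries. The premise is that
a compound sharing an enriched scaffold with known actives of a
disease-associated target is a plausible repurposing candidate; the
output is a hit table to triage, not a ranking model.

## Retrieval model

Each public resource is treated as a *payload dialect*, not a guaranteed
service: parsers are written against the documented payload shapes and
tested exclusively on canned files served by a `FixtureTransport` keyed
on request URL. A `LiveTransport` (stdlib urllib, 3 retries with
exponential backoff, 60 s timeout — the common 2 s client default is
insufficient for these endpoints) exists for live use but nothing in the
test or acceptance path touches the network. Responses outside the
2xx status class are dropped and logged rather than parsed.

Pagination follows the offset/limit convention: the first page's
`total_count` fixes `ceil(total_count / page_size)` iterations at
offsets 0, page_size, 2·page_size, …, which provably fetches every
record exactly once (property-tested exhaustively for totals ≤ 50 and
page sizes ≤ 7).

The UniProt↔Open Targets bulk mapping is ingested from an exported TSV
rather than per-entry calls. Where one gene maps to several accessions,
reviewed entries win, then file order — the upstream sources do not
specify a rule, so we chose the deterministic one that prefers curated
records.

PDB experimental properties (method, resolution, R-factor, space group,
model count) are parsed from the header records of PDB-format text;
unparseable headers leave null fields and keep the entry.

## Curation

Standardization runs in a fixed order: (1) stereo removal, (2–3) salt
stripping with the removed fragments listed, (4) charge neutralization,
(5) element whitelist (H, C, N, O, F, Br, I, Cl, P, S), (6)
InChI/InChIKey/canonical SMILES. Design choices within that frame:

- **Stereo removal on the graph.** Stereo flags are cleared on the
  molecular graph and the molecule re-canonicalized, rather than
  deleting `@ / \` characters from the SMILES text; the outcome is the
  same but the graph operation cannot corrupt directional ring bonds.
- **Salt list.** A packaged fragment list (halide and
  alkali/alkaline-earth counter-ions, sulfate/nitrate/phosphate, common
  solvents) classifies extra fragments of a multi-fragment input. If
  several non-salt fragments remain, the one with the most heavy atoms
  is kept (ties: molecular weight, then canonical SMILES). A
  single-fragment input is never stripped; an input that is *only*
  salts is a normalization failure.
- **Neutralization** uses protonation adjustment only; charges that
  cannot be removed without changing bonds (quaternary nitrogen) are
  kept and the record flagged permanently charged. Only valence sanity
  is checked beyond that — no geometry/clash checks, since the package
  handles 2D graphs exclusively.
- **Aromaticity** is perceived once at parse time and re-applied after
  the last edit by a canonical-SMILES round trip, so standardization,
  scaffold extraction and substructure matching all share one model.
- Failures are never dropped: a rejected record carries one of
  `unparseable | element_filter | normalization_failure` and lands in a
  quarantine table.

Compound identity and deduplication use the InChIKey (not the raw
SMILES string), so the same chemical entity arriving from different
sources merges to a single row.

## Activity labeling

All endpoint types (Ki, IC50, Km, EC50, …) are mixed on the common pX
scale, pX = −log₁₀(molar value); a config switch can restrict the
endpoint set but the default mirrors the mixed-endpoint practice of the
upstream sources. The binary label is strict: active ⇔ pX > cutoff.
The default cutoff is 9 (sub-nanomolar); 6 (sub-micromolar) is the
recommended setting for membrane transporters, whose characteristic
activity range is weaker. At exactly the cutoff a compound is inactive —
with "greater than" semantics the boundary case falls on the inactive
side, and we apply the same strictness at both cutoffs.

Censored measurements (paper sources are silent on these): `=` rows are
labeled directly; a `<` bound is kept only when it forces activity
(e.g. "< 1 nM" at cutoff 9), a `>` bound only when it forces
inactivity; anything uninformative is flagged and excluded. Multiple
measurements per (target, ligand) reduce to the median of their binary
labels; an even split (median 0.5) is *not* active, consistent with
keeping only label-1 ligands. PDB-derived ligands carry no label and
enter the active set unconditionally, with provenance recorded.

## Scaffolds, distances, clustering

The Bemis–Murcko scaffold keeps ring systems and their connecting
linkers; ring-free molecules have no scaffold and drop out. Scaffolds
consisting of a single ring (aromatic or not — we generalized the usual
"single aromatic ring" example, with the ring-count threshold
configurable) are too generic to discriminate and are filtered before
clustering.

Similarity is the size m of the maximum common *connected* substructure
under element-identity matching where aromatic bonds match only
aromatic bonds and rings need not be complete. The distance is the
atom-count Tanimoto

    d(a, b) = 1 − m / (|a| + |b| − m)

which is symmetric, 0 for identical scaffolds and 1 for scaffolds
sharing no atom (an alternative 1 − m/max(|a|,|b|) is available via
config). The underlying MCS node used in the original KNIME realization
does not document its exact formula, so the formula is an explicit
package choice, reported in run logs. Example: naphthalene vs quinoline
share m = 9 atoms of 10 + 10, giving d = 1 − 9/11 ≈ 0.182. A per-pair
5 s MCS timeout returns the best pattern found, flagged approximate.

Clustering is agglomerative with average linkage (configurable to
single/complete; the source workflow names only "hierarchical
clustering") on the condensed distance matrix, cut at distance 0.5.
Determinism: scaffolds are sorted by canonical SMILES before the matrix
is built, and cluster ids are assigned in order of first member, so the
result is invariant to input order. A single scaffold short-circuits to
one singleton cluster with no matrix computation. Clustering runs
independently per target.

## Query generation and screening

Per cluster: a singleton's query is the scaffold rendered as SMARTS;
multi-member clusters take the multi-molecule MCS over all members,
computed in one deterministic multi-molecule search (not iterative
pairwise folding, which loses exactness once an intermediate becomes a
query pattern) and verified — every emitted query must match every
member scaffold, or generation fails loudly. Queries below
`min_query_size` (default 3 heavy atoms) are suppressed as vacuous;
duplicate patterns within a target are merged. The emitted dialect is
element-number atoms (`[#6]`, `[#7]`, …) with explicit bonds, `:` for
aromatic; no hybrid `-,:`-style bond expressions are written (each bond
gets its perceived order), and no recursive SMARTS or charge/H-count
constraints.

Eighteen published reference patterns in this dialect (five named
clusters: open-chain keys, nucleoside analogs, miscellaneous,
cyclopropane, adamantane) ship as `data/table2.smarts` with per-pattern
hit counts; the packaged copy is transcribed text, and the procedure
that grouped them into named clusters was editorial upstream and is not
reproduced here.

Screening matches each query against each standardized library compound
under the same aromaticity model; a compound matched by k queries
yields k hit rows, with matched atom indices recorded for SVG
highlighting. Cross-library overlap intersects hit InChIKeys across all
screened libraries. The rediscovery fraction is rediscovered unique
compounds over unique hit compounds (undefined for an empty hit list).
Because hit-count conventions are ambiguous, both (compound, query) row
counts and unique-compound counts are reported.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
tested:

- **Library**: 5 seed scaffold families × 8 analogs + 50 ring-free
  decoys. The default seeds (adamantane, quinazoline, 1,3-benzodioxole,
  phenylpiperazine, a purine-nucleoside core) are multi-ring frameworks
  — single rings would fall to the genericity filter — chosen so all
  pairwise distances exceed the 0.5 threshold, making
  one-cluster-per-family the ground truth. Analogs add 1–3 substituents
  (methyl, ethyl, hydroxyl, amino, fluoro, methoxy, carboxyl — all
  within the element whitelist) at ring carbons, which keeps the Murcko
  framework exactly the seed, so recovery is decidable by construction.
  15 % of records carry a salt fragment, 20 % a stereocenter, 15 % a
  neutralizable charge, to exercise every curation step.
- **Bioactivities**: members of active families draw pX from
  N(9.5, 0.1), everything else from N(5.0, 0.5), 3 replicates per
  compound at cutoff 9 — the active median sits 5 σ above the cutoff
  and the inactive tail ~8 σ below it, so planted labels are effectively
  deterministic while still exercising the median.
- **Payload fixtures**: one complete canned directory per run —
  association JSON, UniProt XML with PDB cross-references,
  best-structures JSON, RCSB entry/chemcomp JSON (including a
  blocklisted co-crystallization agent), PDB header text, paginated
  activity XML with a constant `total_count` and a ragged last page
  (2410 records / page size 1000 → 3 pages by default), IUPHAR
  interaction JSON, and a PubChem AID→CID chain file.

All generators are pure functions of (spec, seed): identical seeds give
byte-identical files. What the generators deliberately do **not**
emulate: drug-likeness or property-matched decoys, assay noise
structure, endpoint heterogeneity, or the scale and redundancy of real
libraries. Passing the recovery study therefore demonstrates the
correctness of the machinery (curation, clustering, query generation,
matching), not screening enrichment on real pharmacology data — the
original studies' headline hit counts depend on live database state and
licensed libraries and are out of scope by design.

## Numerical and degenerate-input choices

- Pagination of 0 records is an empty plan; a fixture page may be empty
  while still declaring the total.
- MCS of bond-free pairs falls back to the single-atom common
  substructure (smallest shared atomic number), size 1; disjoint
  element sets give size 0 and distance 1.
- Distance-matrix construction validates symmetry, zero diagonal and
  the [0, 1] range at construction time.
- Ties anywhere (fragment keeping, scaffold ordering, cluster ids,
  merge output) break on canonical SMILES / sorted keys, never on hash
  or insertion order.
- Oracle tests (brute-force subgraph monomorphism and common-edge-subset
  enumeration via networkx) cover molecules ≤ 12 heavy atoms, where
  exhaustive enumeration is exact and fast; the MCS oracle corpus is
  16 ring systems, all pairs ≤ 10 atoms.

## Known limitations

- No tautomer canonicalization, protonation-state enumeration, or 3D
  anything; identity is 2D-graph-based.
- The "Advanced" quality checks of the upstream normalization tooling
  are not enumerated anywhere public; only valence sanity is applied.
- Live-endpoint URL templates reflect the documented (partly deprecated)
  REST forms; parsers target the payload shapes, not service uptime.
- Hybrid bond expressions in the packaged reference patterns (`-,:`,
  `:,-`) are preserved verbatim; two patterns containing `-:`/`:-`
  conjunctions parse but cannot match any bond, which is how they are
  printed upstream.
- `is_too_generic` counts SSSR rings; exotic cage systems may count
  differently than visual inspection suggests.
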