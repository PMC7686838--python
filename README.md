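# scaffquery

Ligand-based in-silico drug repurposing: harvest target→ligand evidence
from public-resource payloads, standardize and label the compounds, mine
enriched Bemis–Murcko scaffolds into maximum-common-substructure (MCS)
SMARTS queries, and screen drug libraries by substructure to nominate
repurposing candidates.

## Who this is for

Computational chemists and data miners who want an offline-runnable,
tested implementation of the classic ligand-based repurposing loop:

1. **Targets** — disease → protein targets via an association payload
   (score threshold, e.g. ≥ 0.99), or a user-supplied UniProt list.
2. **Ligands** — co-resolved PDB ligands (entry → bound components →
   component SMILES) plus bioactivity measurements from ChEMBL-, PubChem-
   and IUPHAR-shaped payloads, fetched with correct pagination
   (`ceil(total_count / 1000)` iterations over the `offset` parameter).
3. **Curation** — six-step standardization: stereo removal, salt
   stripping, fragment listing, charge neutralization, an
   H/C/N/O/F/Br/I/Cl/P/S element filter, and InChI/InChIKey/canonical-
   SMILES identity. Rejected records go to a quarantine table, never
   silently dropped.
4. **Labels** — measurements mapped to the pX scale
   (pX = −log₁₀ of the molar value, so 1 nM ⇔ 9), binary activity at a
   strict cutoff (pX > 9 by default; pX > 6 suits transporter targets),
   median-aggregated per (target, ligand), merged across sources.
5. **Scaffolds → queries** — Bemis–Murcko frameworks of the actives,
   single-ring ("too generic") frameworks filtered out, MCS-based
   distances d = 1 − m/(|a|+|b|−m), average-linkage hierarchical
   clustering cut at distance 0.5, and one SMARTS query per cluster
   (the multi-molecule MCS; the scaffold itself for singletons).
6. **Screening** — substructure search of SDF / SMILES-CSV libraries,
   hit tables with matched-atom highlights (SVG), cross-library overlap,
   and rediscovery accounting.

All parsers run on canned payload files, so the whole pipeline works
with no network; 18 published reference query patterns ship with the
package (`scaffquery.load_reference_queries()`).

## Worked example

Generate a synthetic study — 5 planted scaffold families × 8 analogs
plus 50 scaffold-free decoys, with salts/stereo/charges planted to
exercise curation — then run the pipeline end to end:

```python
import dataclasses
from scaffquery import (
    ChemotypeLibrarySpec, generate_chemotype_library,
    generate_bioactivity_table, standardize_all, label_records,
    aggregate_by_ligand, merge_active_set, cluster_target_scaffolds,
    generate_queries, substructure_screen,
)
from scaffquery.scaffolds import scaffolds_for_target, filter_generic

spec = ChemotypeLibrarySpec(rng_seed=2020)
library, truth = generate_chemotype_library(spec)
std, rejected = standardize_all(library)

acts = generate_bioactivity_table(library, truth, rng_seed=11)
key = {r.source_id: r.inchikey for r in std}
for a in acts:
    a.ligand_key = key.get(a.molecule_id)
label_records(acts, cutoff=9.0)
actives = merge_active_set(
    [aggregate_by_ligand(acts, cutoff=9.0)], [],
    {r.inchikey: r.canonical_smiles for r in std},
)
pairs = [(r.inchikey, r.smiles) for r in actives.itertuples()]
scaffolds = filter_generic(scaffolds_for_target(pairs, uniprot_id="P99999"))
clusters = cluster_target_scaffolds(scaffolds, threshold=0.5)
queries = generate_queries(clusters)
print(len(actives), len(clusters), len(queries))

held, held_truth = generate_chemotype_library(dataclasses.replace(spec, rng_seed=777))
hits = substructure_screen(standardize_all(held)[0], queries, "heldout")
analogs = {i for i, v in held_truth.items() if v != "decoy"}
found = {h.compound_id for h in hits}
print(len(found & analogs) / len(analogs), len(found - analogs))
```

This prints:

```
40 5 5
1.0 0
```

40 unique actives collapse to 5 scaffold clusters and 5 SMARTS queries
(one per planted family); screening a freshly generated held-out library
recovers 100 % of the planted analogs and none of the ring-free decoys.

The same flow is available from the shell:

```bash
scaffquery synth --out study --seed 2020
scaffquery run --config run.json      # fixtures + libraries + thresholds
scaffquery screen --queries out/queries.smarts --library drugbank.sdf \
    --library cas.csv --actives out/actives.tsv --out hits/
```

## Layout

| module | role |
| --- | --- |
| `scaffquery.retrieval` | request builders, status classes, pagination, the five payload parsers, fixture/live transports |
| `scaffquery.chemstruct` | six-step standardization, identity, SDF/CSV I/O |
| `scaffquery.bioactivity` | pX transform, labeling, median aggregation, merging |
| `scaffquery.scaffolds` | Murcko extraction, genericity filter, MCS distances, clustering |
| `scaffquery.queries` | per-cluster SMARTS generation + packaged reference queries |
| `scaffquery.screen` | substructure screening, overlap, rediscovery, SVG highlights |
| `scaffquery.synthetic` | ground-truth libraries, bioactivity tables, API payload fixtures |
| `scaffquery.cli` | `RunConfig`, `run_pipeline`, the `scaffquery` command |

See `docs/methods.md` for the model choices, parameters and limitations.
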