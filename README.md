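# lincskit

Data and metadata management toolkit for multi-center perturbation-response
screening consortia, modeled on the coordination workflow of the LINCS
program (Library of Integrated Network-based Cellular Signatures). Several
independent centers run different assays on shared reagents — small
molecules, cell lines, antibodies — and a coordination hub must turn their
heterogeneous submissions into harmonized, citable, FAIR dataset packages.
`lincskit` implements that hub's pipeline as a reusable library and CLI:

* **Metadata specifications** — four machine-readable specification
  families shipped as data: 11 reagent categories, 6 experimental
  categories, a common assay core with per-assay extensions, and a single
  37-descriptor dataset category. Every field carries an importance tier
  (1 = required, 2 = recommended, 3 = optional) and, where appropriate, a
  controlled vocabulary.
* **Validation** — center submissions (CSV/TSV/JSON) are mapped from
  center-specific field names to the official labels and checked for
  required-field completeness, vocabulary membership, value typing, and
  reference integrity against the registry.
* **Registry** — canonical reagent entities with persistent prefixed
  identifiers (`LSM-000001` style), deduplicated on a canonical key;
  center-scoped batches track the physical samples; cell lineages
  (primary cell → iPSC → differentiated cell) inherit metadata along the
  parent chain. Dataset groups (LDG) hold per-data-level datasets (LDS),
  level 1 = raw through level 4+ = signature. The ledger is event-sourced:
  replaying the JSON-lines log reconstructs identical state, and
  identifiers are never reissued, even after withdrawal.
* **Structure standardization** — submitted SMILES/SDF pass through salt
  and addend stripping, charge neutralization, canonical tautomer
  selection and InChIKey generation (RDKit), so a free base and its
  hydrochloride salt register as one compound. Failures land in an
  exception queue for manual resolution, never silently.
* **Bioactivity curation** — ChEMBL-style activity tables are filtered
  (confidence ≥ 5; binding/functional assays; endpoints Potency, IC50,
  Kd, Ki, Activity, EC50, AC50; concentration-response only),
  p-transformed (−log10 molar), and averaged per compound–target–endpoint
  group. Offline per-source resolvers attach external identifiers and
  gene symbols.
* **Packaging** — a released dataset is a six-component container
  (manifest, data files, reagent metadata, assay + experimental metadata,
  dataset metadata, processing-pipeline specs) with SHA-256 digests,
  deterministic rebuilds, resolvable identifier URLs and a data-citation
  record (authors, title, year, repository, resource type, version,
  identifier).

A seeded fixture generator (`lincskit.synth`) fabricates submissions with
planted defects, structure families with known canonical groups, and
activity tables with known aggregates, so the whole pipeline is testable
offline.

## Worked example

```sh
lincskit fixtures    --seed 1 --out work
lincskit validate    work/submissions.csv --family reagent \
                     --category "Small molecules" --accept-warnings
lincskit standardize work/structures.smi --out work/standardized.tsv
lincskit register    --submissions work/submissions.csv \
                     --standardized work/standardized.tsv \
                     --ledger work/ledger.jsonl
lincskit aggregate   work/activities.tsv --ledger work/ledger.jsonl \
                     --resolver-dir work/resolvers --out work/aggregated.tsv
lincskit package     --ledger work/ledger.jsonl --bundle work \
                     --out work/packages
lincskit verify      work/packages/LDS-000001
```

prints (stderr log interleaved):

```
wrote fixture bundle (seed 1) to work
20 record(s): PASS (0 error(s), 0 warning(s))
20/20 standardized, 0 in exception queue
registered 5 new canonical entities, 20 input rows
21 records -> 16 retained -> 5 aggregates (6 rejected)
built and verified work/packages/LDS-000001
A. Example (2017). Synthetic perturbation profiling run (seed 1). Example Data Portal. Dataset, version 1. https://identifiers.example/lincs.data/LDS-000001
6 record(s): PASS (0 error(s), 0 warning(s))
```

Reading the numbers: the fixture bundle contains 20 small-molecule
submissions spanning 5 structure families (each submitted as free base,
hydrochloride, sodium carboxylate and protonated form), so registration
consolidates 20 batches onto 5 canonical entities. The 21-row activity
table carries 15 clean records in 5 compound–target–endpoint groups plus
6 decoys, one per curation criterion; all 6 are rejected and the 5 group
means in `work/aggregated.tsv` equal the planted truth. The package under
`work/packages/LDS-000001` verifies: all six component roles present and
every digest intact.

The same flow is available as library calls:

```python
from lincskit import standardize, structure_key, RegistryLedger

ledger = RegistryLedger()
for smiles in ["NCCc1ccc(O)c(O)c1", "NCCc1ccc(O)c(O)c1.Cl"]:
    record = standardize(smiles)
    print(ledger.register_reagent("Small molecules", structure_key(record)))
# LSM-000001
# LSM-000001   <- the salt form resolves to the same canonical entity
```

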