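# Methods

## The model: a coordination hub for multi-center screens

The toolkit implements the data-management workflow of a consortium in
which independent data-generation centers submit reagent, experimental,
assay and dataset metadata plus data files of arbitrary formats to a
coordination hub. The hub's job is (1) to validate submissions against
shared specifications, (2) to standardize reagents onto canonical
representations with persistent identifiers so datasets from different
centers integrate, (3) to enrich compounds with curated bioactivity and
external cross-references, and (4) to release harmonized, checksummed,
citable dataset packages. The pipeline stages are pure functions over an
event-sourced registry, so every run is replayable and auditable.

## Metadata specifications

The four specification families are data, not code: one YAML document per
family plus flat one-term-per-line vocabulary files, loaded into frozen
`FieldSpec`/`CategorySpec` objects at startup. The census is fixed by the
published specification structure — 11 reagent categories, 6 experimental
categories (the five cell reagent categories share one experimental
category, since culture conditions do not depend on how the cell was
derived), a common assay core with named per-assay extensions, and a
single dataset category of exactly 37 descriptors — and is re-checked at
load time, so a corrupted bundle fails fast naming the family.

Only a subset of field names is fixed by the published description (the
small-molecule vendor triple at tier 1, the cell-line donor block at tier
2, the dataset attribution fields); the remaining descriptors needed to
reach the printed counts are plausible domain fields chosen by this
package and are marked `provenance: implementer-defined` in the YAML so
the schema is honest about which names are load-bearing.

Importance is stored as the integer coding 1/2/3 (required / recommended /
optional) rather than an enum, matching how the tiers are printed.

## Validation semantics

* An importance-1 field that is absent or blank is an error; the explicit
  sentinel `N/A` counts as provided (the specifications do not distinguish
  "unknown" from "does not apply", so a deliberate token is the auditable
  choice). Importance-2 omissions are warnings and never block on their
  own; the `--accept-warnings` flag is the CLI stand-in for the pipeline's
  manual-review checkpoint.
* Vocabulary matching is exact after whitespace trimming and Unicode NFC
  normalization. No fuzzy matching: validation must be reproducible and
  auditable, and near-miss acceptance would hide center-side defects.
* Reference fields (`LINCS ID`, `Parent Cell ID`, `Reagent Batch ID`) are
  checked against the ledger when one is supplied; a dangling reference is
  an error because formal submission requires prior registration.
* The issue-code set extends the obvious five with `MISSING_RECOMMENDED`
  so that `MISSING_REQUIRED` can be unconditionally an error while
  importance-2 omissions remain warnings.

## Registry and identifiers

Canonical entities are deduplicated per reagent kind on a canonical key:
the standardized InChIKey for small molecules, a normalized name/accession
key for other kinds (the structure-based path is only defined for
chemistry). Identifier format is `<PREFIX>-<zero-padded counter>` with a
configurable width (default 6); each of the 11 reagent categories has its
own prefix, plus `LDG`/`LDS` for groups and datasets. Counters are
strictly monotone and identifiers are never reused: deletion is
tombstoning, which preserves citability of anything ever released.

All mutation flows through an event log (JSON lines, one event per line);
the materialized dictionaries are a pure fold over it, which gives the
serialize/reload identity and the audit trail for free. A SQLite export
mirrors the hybrid key-value + relational design of the production
system: the events table is the source of truth, the relational tables a
query convenience.

Cell provenance is a parent pointer restricted to the five cell
categories, with cycle rejection by ancestor walk. Inherited metadata is
resolved root-first so the nearest ancestor (and finally the cell itself)
wins on conflicts, and the stored records are never rewritten — the
lineage captures each fact once.

Data levels follow the harmonized abstraction tiers: 1 raw, 2 processed,
3 normalized, 4 signature; levels above 4 are accepted as signature-like
extensions. A group may hold several datasets of one level only under
distinct flavor labels.

## Structure standardization

The rule sequence is parse → salt/addend stripping → charge
neutralization → canonical tautomer → canonical SMILES + InChI/InChIKey,
on RDKit (the production systems used commercial toolchains; the rule
sequence, not the vendor, is the contract).

* The salt list is an editable data file of canonical fragment SMILES
  seeded with common pharmaceutical counterions. Stripping applies only
  to multi-fragment inputs; when every fragment is on the list there is
  no organic parent, so the largest fragment is kept and the record is
  routed to the exception queue. Fragments that can plausibly be the
  parent of a single-compound submission (acetic acid, simple alcohols)
  are deliberately not listed — their ionic forms are handled by
  neutralization instead.
* Neutralization is atom-local: anions that can accept a proton gain one,
  protonated centers carrying hydrogens lose one; charge-separated groups
  (nitro) and permanent cations (quaternary N) are preserved, the latter
  flagged `residual-charge` rather than failed.
* Tautomer choice delegates to RDKit's canonical tautomer with sp3- and
  double-bond-stereo removal disabled. The contract tested is
  determinism, idempotence and formula preservation — not a particular
  tautomer, which is a toolkit-internal convention.
* Stereochemistry passes through verbatim and deduplication uses the full
  InChIKey, so stereoisomers register separately; `structure_key(...,
  connectivity_only=True)` collapses to the skeleton block where a
  coarser grouping is wanted.

Every input ends as exactly one of: an `ok` record, or an exception-queue
entry naming the failing checkpoint; resolved entries re-enter the
pipeline.

## Bioactivity curation

The retention predicate is the conjunction: confidence ≥ 5, assay type ∈
{binding, functional}, endpoint ∈ {Potency, IC50, Kd, Ki, Activity, EC50,
AC50} (matched case- and subscript-insensitively), concentration-response
data only. Records with censored relations (`>`, `<`) are additionally
excluded by default behind a switch, since a censored concentration does
not average meaningfully. Rejections log the first failing criterion in a
fixed check order.

The p-transform is −log10 of the value in molar; the unit table is the
exact decade set {M, mM, µM, nM, pM} (micro sign and Greek mu both
accepted), and anything else — mass units, percentages — is a per-record
rejection, consistent with curating concentration-response endpoints
only. Aggregation groups by (LSM ID, target, endpoint) and takes the
arithmetic mean over sorted member p-values (sorted summation makes the
result bit-identical under input shuffles); duplicates are kept — each
submitted record contributes once, because deduplicating "identical"
assay results would require assay-identity information the input does not
carry. Output rows are sorted by group key.

Cross-reference resolvers are pure offline lookup tables per source,
standing in for the production web services; unknown keys return empty
results and are logged, never raised. When a center submitted its own
external identifier and the resolver disagrees, the pair is surfaced as a
conflict for human resolution rather than silently overwritten. Resolver
fixtures carry a `source_version` label (default "22") recorded in output
provenance.

## Packaging

A package directory holds the six component roles; the manifest is JSON
with ordered entries (path, role, SHA-256, bytes) and a fixed epoch
timestamp, so rebuilding from identical registry state is byte-identical.
Payload files are verified against their registered digests before
copying and refused on mismatch; packages are only built from clean
registry state. Metadata files inside packages are TSV with the official
field labels as header; assay and experimental metadata are two files
under one component role. Identifier URLs are `<namespace>/<id>` with the
namespace as configuration, so resolution targets can change without
touching identifiers. The citation record (authors, title, year,
repository, resource type, version, identifier URL) is derived entirely
from dataset metadata; gaps are reported together in one error.

## Synthetic fixtures

The generator emulates the *shapes* of center data: submission tables in
the spec dialects with a controlled planted-defect fraction (each
defective record carries exactly one defect and its expected issue code);
structure families built from amino-acid-like parents of increasing chain
length, each submitted as free molecule, hydrochloride, sodium
carboxylate and N-protonated salt; activity tables on decade
concentration grids with per-group means known by construction, plus
exactly one decoy per curation criterion. All randomness comes from one
seeded `random.Random`; a seed reproduces a bundle byte for byte.

What passing these fixtures does *not* show: real submissions have
messier typography, real structures exercise far more of tautomer and
salt space than the seeded families, and real bioactivity values are not
on decade grids. The fixtures verify the contracts (detection,
consolidation, exact aggregation), not robustness to the full diversity
of production data.

Default problem sizes — 20-submission bundles, 25–50 structure families,
500-record activity tables, 1000-identifier mint runs — are chosen so the
full suite and the acceptance script each run in seconds on one core
while still exercising every code path and oracle at non-trivial
cardinality.

## Known limitations

* Assay metadata is modeled as a common core plus named extensions; the
  per-assay extension catalog ships with two examples and no claim of a
  fixed assay count.
* No ontology reasoning: vocabularies are flat term lists.
* Single-writer persistence; no concurrency control beyond transactional
  file replacement in the CLI.
* Scientific plausibility (dose ranges, sequence validity) is out of
  scope for validation — spec conformance and referential integrity only.
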