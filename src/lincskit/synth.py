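"""Deterministic synthetic fixtures for every pipeline stage.

Real center submissions, vendor structure files and ChEMBL extracts cannot
be bundled, so this module fabricates inputs with known ground truth:

* **submissions** — records against the built-in specifications, fully
  populated and valid, with a controlled fraction carrying exactly one
  planted defect (missing required field, bad vocabulary term, unknown
  field, dangling reference), each labeled with the issue code a validator
  must raise;
* **structure families** — one parent molecule per family plus salt /
  protonation-state variants that must all standardize onto the parent's
  InChIKey;
* **activity tables** — bioactivity records on decade concentration grids
  with per-group mean p-values known by construction, plus one decoy per
  curation criterion that must be filtered out;
* **resolver tables** — per-source lookup fixtures for the offline
  cross-reference resolvers.

All draws come from one named, explicitly seeded generator; a given seed
reproduces the bundle byte for byte. The values emulate the *shapes* of
real data (field dialects, unit grids, salt forms), not real assay biology
or LINCS value distributions.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import ActivityRecord, p_transform
from .spec_model import SpecRegistry, get_category
from .validator import SubmissionRecord, NOT_APPLICABLE

#: defect kinds plantable in a submission, with the issue code each implies
DEFECT_CODES = {
    "missing_required": "MISSING_REQUIRED",
    "bad_vocabulary_term": "BAD_VOCABULARY_TERM",
    "unknown_field": "UNKNOWN_FIELD",
    "dangling_reference": "UNREGISTERED_REFERENCE",
}

_SUBMISSION_CATEGORIES = (
    ("reagent", "Small molecules"),
    ("reagent", "Cell lines"),
    ("reagent", "Proteins"),
    ("reagent", "Antibody reagents"),
    ("reagent", "Nucleic acids reagents"),
)


def _value_for(fieldspec, registry: SpecRegistry, rng: random.Random):
    kind = fieldspec.value_kind
    if kind == "vocabulary":
        return rng.choice(registry.vocabulary_terms(fieldspec.vocabulary_ref))
    if kind == "integer":
        return str(rng.randint(1, 90))
    if kind == "decimal":
        return str(rng.choice([0.1, 0.5, 1.0, 3.0, 10.0, 30.0]))
    if kind == "date":
        return f"20{rng.randint(10, 17):02d}-{rng.randint(1, 12):02d}-01"
    if kind == "url":
        return f"https://example.org/resource/{rng.randint(1000, 9999)}"
    if kind == "identifier":
        return f"X{rng.randint(100000, 999999)}"
    return f"value-{rng.randint(1000, 9999)}"


def generate_submissions(registry: SpecRegistry, n: int,
                         error_rate: float, seed: int,
                         center_id: str = "CENTER-A",
                         ) -> tuple[list[SubmissionRecord], list[str | None]]:
    """``n`` reagent submissions; ~``error_rate`` of them carry one defect.

    Returns the records plus parallel truth labels: the expected issue
    code, or None for a clean record. Reference-valued fields of clean
    records carry the "not applicable" sentinel so validation does not
    depend on prior registry state.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = random.Random(seed)
    n_defective = round(n * error_rate)
    defect_kinds = list(DEFECT_CODES)
    records: list[SubmissionRecord] = []
    labels: list[str | None] = []
    for i in range(n):
        family, cat_name = _SUBMISSION_CATEGORIES[i % len(_SUBMISSION_CATEGORIES)]
        category = get_category(registry, family, cat_name)
        values = {}
        for f in category.fields:
            if f.name in ("LINCS ID", "Parent Cell ID"):
                values[f.name] = NOT_APPLICABLE
            else:
                values[f.name] = _value_for(f, registry, rng)
        label: str | None = None
        if i < n_defective:
            kind = defect_kinds[i % len(defect_kinds)]
            label = DEFECT_CODES[kind]
            if kind == "missing_required":
                target = rng.choice(
                    [f for f in category.fields if f.importance == 1])
                values[target.name] = ""
            elif kind == "bad_vocabulary_term":
                vocab_fields = [f for f in category.fields
                                if f.value_kind == "vocabulary"]
                if vocab_fields:
                    values[rng.choice(vocab_fields).name] = "no-such-term"
                else:  # category without vocabulary fields: fall back
                    label = DEFECT_CODES["unknown_field"]
                    values[f"bogus_column_{rng.randint(10, 99)}"] = "x"
            elif kind == "unknown_field":
                values[f"bogus_column_{rng.randint(10, 99)}"] = "x"
            elif kind == "dangling_reference":
                values["LINCS ID"] = "LSM-999999"
        records.append(SubmissionRecord(
            family=family, category=cat_name, center_id=center_id,
            values=values,
            batch_id=values.get("Center-specific Reagent ID")))
        labels.append(label)
    return records, labels


def generate_structure_families(k_families: int, seed: int,
                                ) -> tuple[list[str], list[int]]:
    """SMILES list with family labels; one shared canonical form per family.

    Each family is built from an amino-acid-like parent ``N(C)nC(=O)O``
    (carbon chain length grows with the family index, so parents never
    collide) in four submitted forms: the free molecule, its hydrochloride
    salt, the deprotonated sodium carboxylate, and the N-protonated
    chloride. Standardization must map all four onto the parent InChIKey.
    """
    if k_families < 1:
        raise ValueError("k_families must be >= 1")
    rng = random.Random(seed)
    smiles: list[str] = []
    labels: list[int] = []
    for fam in range(k_families):
        chain = "C" * (fam + 1)
        parent = f"N{chain}C(=O)O"
        variants = [
            parent,
            parent + ".Cl",
            f"N{chain}C(=O)[O-].[Na+]",
            f"[NH3+]{chain}C(=O)O.[Cl-]",
        ]
        for v in variants:
            smiles.append(v)
            labels.append(fam)
    order = list(range(len(smiles)))
    rng.shuffle(order)
    return [smiles[i] for i in order], [labels[i] for i in order]


#: concentration grid (value, unit) pairs with exact decade p-values
_DECADE_GRID = [(1.0, "nM"), (10.0, "nM"), (100.0, "nM"),
                (1.0, "uM"), (10.0, "uM"), (1.0, "pM"), (100.0, "pM")]

_ENDPOINT_CYCLE = ("IC50", "Ki", "EC50", "Potency", "Kd", "AC50", "Activity")


def generate_activity_table(n_groups: int, records_per_group: int, seed: int,
                            compound_keys: list[str] | None = None,
                            with_decoys: bool = True,
                            ) -> tuple[list[ActivityRecord], dict[str, str],
                                       dict[tuple[str, str, str], tuple[float, int]]]:
    """Bioactivity records with known aggregates.

    Returns ``(records, compound_to_lsm, truth)`` where ``truth`` maps each
    (LSM ID, target, endpoint) group to its expected mean p-value and
    member count. With ``with_decoys`` the table additionally contains one
    record violating each curation criterion (low confidence, wrong assay
    type, wrong endpoint, non-concentration-response, censored relation,
    unconvertible units); none of these may survive curation.
    """
    rng = random.Random(seed)
    records: list[ActivityRecord] = []
    compound_to_lsm: dict[str, str] = {}
    truth: dict[tuple[str, str, str], tuple[float, int]] = {}
    for g in range(n_groups):
        key = (compound_keys[g % len(compound_keys)] if compound_keys
               else f"CMPD-{g + 1:04d}")
        lsm = f"LSM-{g + 1:06d}"
        compound_to_lsm.setdefault(key, lsm)
        target = f"CHEMBL{2000 + g % 7}"
        accession = f"P{10000 + g % 7:05d}"
        endpoint = _ENDPOINT_CYCLE[g % len(_ENDPOINT_CYCLE)]
        p_values = []
        for _ in range(records_per_group):
            value, units = rng.choice(_DECADE_GRID)
            records.append(ActivityRecord(
                compound_key=key, target_id=target,
                target_accession=accession, endpoint=endpoint,
                value=value, units=units,
                confidence=rng.choice([5, 6, 7, 8, 9]),
                assay_type=rng.choice(["binding", "functional"])))
            p_values.append(p_transform(value, units))
        truth[(compound_to_lsm[key], target, endpoint)] = (
            sum(p_values) / len(p_values), records_per_group)
    if with_decoys:
        base = dict(compound_key=next(iter(compound_to_lsm))
                    if compound_to_lsm else "CMPD-0001",
                    target_id="CHEMBL9999", target_accession="P99999",
                    endpoint="IC50", value=10.0, units="nM",
                    confidence=9, assay_type="binding")
        records.append(ActivityRecord(**{**base, "confidence": 4}))
        records.append(ActivityRecord(**{**base, "assay_type": "ADMET"}))
        records.append(ActivityRecord(**{**base, "endpoint": "Solubility"}))
        records.append(ActivityRecord(
            **{**base, "is_concentration_response": False}))
        records.append(ActivityRecord(**{**base, "relation": ">"}))
        records.append(ActivityRecord(**{**base, "units": "kg"}))
        compound_to_lsm.setdefault(base["compound_key"], "LSM-000001")
    rng.shuffle(records)
    return records, compound_to_lsm, truth


def generate_resolver_tables(seed: int, canonical_keys: list[str],
                             accessions: list[str] | None = None,
                             ) -> dict[str, dict[str, tuple[str, ...]]]:
    """Per-source lookup fixtures covering the given canonical keys.

    Compound sources (PubChem, ChEMBL, ChEBI) cover all keys; the sparser
    sources (DrugCentral, PDB, BindingDB) cover a seeded subset, so lookups
    exercise both populated and empty results. UniProt maps protein
    accessions to synthetic gene symbols.
    """
    rng = random.Random(seed)
    tables: dict[str, dict[str, tuple[str, ...]]] = {}
    dense = {"PubChem": "CID", "ChEMBL": "CHEMBL", "ChEBI": "CHEBI:"}
    sparse = {"DrugCentral": "DC", "PDB": "pdb", "BindingDB": "BDBM"}
    for source, prefix in dense.items():
        tables[source] = {k: (f"{prefix}{rng.randint(10000, 99999)}",)
                          for k in canonical_keys}
    for source, prefix in sparse.items():
        covered = [k for k in canonical_keys if rng.random() < 0.5]
        tables[source] = {k: (f"{prefix}{rng.randint(1000, 9999)}",)
                          for k in covered}
    symbols = {}
    for acc in accessions or []:
        symbols[acc] = (f"GENE{rng.randint(1, 999):03d}",)
    tables["UniProt"] = symbols
    return tables


# -- whole-bundle generation (drives the end-to-end CLI flow) ----------------

@dataclass
class FixtureBundle:
    seed: int
    out_dir: Path
    files: dict[str, str] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def generate_bundle(registry: SpecRegistry, out_dir: Path | str, seed: int,
                    n_submissions: int = 20, error_rate: float = 0.0,
                    k_families: int = 5, n_groups: int = 5,
                    records_per_group: int = 3) -> FixtureBundle:
    """Write a complete fixture set to disk in the pipeline's file dialects.

    Produces small-molecule submissions aligned with structure files (each
    submission's SMILES is a member of a structure family), an activity
    table keyed by the family parents' structures, resolver tables, a
    payload data file, and the dataset metadata needed for packaging. A
    ``truth.json`` records every planted expectation.
    """
    from . import chem  # deferred: RDKit import is heavy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    bundle = FixtureBundle(seed=seed, out_dir=out)

    # structures: families of salt/protonation variants
    smiles, fam_labels = generate_structure_families(k_families, seed)
    struct_lines = [f"S{idx + 1:04d}\t{smi}"
                    for idx, smi in enumerate(smiles)]
    (out / "structures.smi").write_text("\n".join(struct_lines) + "\n")
    bundle.files["structures"] = "structures.smi"

    # submissions: one small-molecule record per structure
    category = get_category(registry, "reagent", "Small molecules")
    sub_rows = []
    for idx, smi in enumerate(smiles):
        values = {}
        for f in category.fields:
            if f.name == "SMILES":
                values[f.name] = smi
            elif f.name == "Center-specific Reagent ID":
                values[f.name] = f"S{idx + 1:04d}"
            elif f.name == "LINCS ID":
                values[f.name] = NOT_APPLICABLE
            elif f.name == "Reagent Name":
                values[f.name] = f"compound-family-{fam_labels[idx]}"
            elif f.name == "Center Name":
                values[f.name] = "CENTER-A"
            else:
                values[f.name] = _value_for(f, registry, rng)
        sub_rows.append(values)
    header = [f.name for f in category.fields]
    csv_lines = [",".join(header)]
    for row in sub_rows:
        csv_lines.append(",".join(str(row.get(h, "")) for h in header))
    (out / "submissions.csv").write_text("\n".join(csv_lines) + "\n")
    bundle.files["submissions"] = "submissions.csv"

    # activities keyed by the standardized family parents
    parent_keys = []
    for fam in range(k_families):
        parent = f"N{'C' * (fam + 1)}C(=O)O"
        parent_keys.append(chem.standardize(parent).inchikey)
    records, _, truth = generate_activity_table(
        n_groups, records_per_group, seed, compound_keys=parent_keys)
    act_lines = ["\t".join(["compound_key", "target_id", "target_accession",
                            "endpoint", "value", "units", "confidence",
                            "assay_type", "is_concentration_response",
                            "relation"])]
    for r in records:
        act_lines.append("\t".join([
            r.compound_key, r.target_id, r.target_accession, r.endpoint,
            f"{r.value:g}", r.units, str(r.confidence), r.assay_type,
            str(r.is_concentration_response).lower(), r.relation]))
    (out / "activities.tsv").write_text("\n".join(act_lines) + "\n")
    bundle.files["activities"] = "activities.tsv"

    # resolver tables
    accessions = sorted({r.target_accession for r in records})
    tables = generate_resolver_tables(seed, parent_keys, accessions)
    resolver_dir = out / "resolvers"
    resolver_dir.mkdir(exist_ok=True)
    for source, table in tables.items():
        lines = [f"{k}\t{e}" for k in sorted(table) for e in table[k]]
        (resolver_dir / f"{source.lower()}.tsv").write_text(
            "\n".join(lines) + "\n")
    bundle.files["resolvers"] = "resolvers"

    # payload: a small level-3 style matrix, plus dataset metadata
    payload_lines = ["sample\t" + "\t".join(f"feature_{j}" for j in range(5))]
    for i in range(10):
        payload_lines.append(
            f"sample_{i}\t" + "\t".join(
                f"{rng.uniform(-3, 3):.4f}" for _ in range(5)))
    (out / "payload_level3.tsv").write_text("\n".join(payload_lines) + "\n")
    bundle.files["payload"] = "payload_level3.tsv"

    dataset_metadata = {
        "Dataset Title": f"Synthetic perturbation profiling run (seed {seed})",
        "Dataset Description": "Synthetic fixture dataset",
        "PI Name": "A. Example",
        "Center Name": "CENTER-A",
        "Grant Number": "U54-000000",
        "Assay Name": "L1000",
        "Data Level": "3",
        "Data Level Role": "normalized",
        "Dataset Release Date": "2017-06-01",
        "Dataset Version": "1",
        "Processing Pipeline": "https://example.org/pipelines/l1000",
        "QC Information": "synthetic fixture, no QC performed",
        "Repository": "Example Data Portal",
        "Resource Type": "Dataset",
    }
    (out / "dataset_metadata.json").write_text(
        json.dumps(dataset_metadata, indent=2, sort_keys=True) + "\n")
    bundle.files["dataset_metadata"] = "dataset_metadata.json"

    bundle.truth = {
        "k_families": k_families,
        "family_labels": fam_labels,
        "n_structures": len(smiles),
        "aggregate_truth": {
            "|".join(k): [v[0], v[1]] for k, v in truth.items()},
    }
    (out / "truth.json").write_text(
        json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n")
    bundle.files["truth"] = "truth.json"
    return bundle
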