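"""Dataset package assembly, verification, identifiers and citations.

A released dataset package is a self-describing container with exactly six
component roles:

1. ``readme_manifest`` — the manifest listing every file with its role,
   SHA-256 digest and size;
2. ``data_files`` — the payload files exactly as submitted (byte-identical
   copies, verified against the registered checksums);
3. ``reagent_metadata`` — one TSV per reagent category used in the
   experiments, each row carrying the canonical registry identifier;
4. ``assay_and_experimental_metadata`` — the assay descriptors and the
   per-reagent experimental conditions (two files under one role);
5. ``dataset_metadata`` — the 37-descriptor dataset record, including the
   processing-pipeline link;
6. ``processing_pipeline_specs`` — the parameter file of the pipeline that
   produced this data level.

Builds are deterministic: entries are ordered, timestamps fixed, so
rebuilding from identical registry state yields an identical manifest.
Identifiers resolve through a configurable namespace
(``<namespace>/<LDS id>``), so the resolution target can move without
changing the identifier itself.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .registry import RegistryLedger, UnregisteredReference
from .spec_model import SpecRegistry, get_category
from .validator import (SubmissionRecord, ValidationIssue, ValidationReport,
                        validate_record)

COMPONENT_ROLES = (
    "readme_manifest", "data_files", "reagent_metadata",
    "assay_and_experimental_metadata", "dataset_metadata",
    "processing_pipeline_specs",
)

MANIFEST_NAME = "manifest.json"

#: fixed timestamp recorded in manifests for build reproducibility
EPOCH_TIMESTAMP = "1970-01-01T00:00:00Z"


class PackagingError(RuntimeError):
    """Refusal to build: dirty registry state or payload mismatch."""


@dataclass
class CitationRecord:
    authors: str
    title: str
    year: str
    repository: str
    resource_type: str
    version: str
    identifier_url: str

    def formatted(self) -> str:
        return (f"{self.authors} ({self.year}). {self.title}. "
                f"{self.repository}. {self.resource_type}, "
                f"version {self.version}. {self.identifier_url}")

    def to_dict(self) -> dict:
        return {"authors": self.authors, "title": self.title,
                "year": self.year, "repository": self.repository,
                "resource_type": self.resource_type, "version": self.version,
                "identifier_url": self.identifier_url}


@dataclass
class DatasetPackage:
    lds_id: str
    path: Path
    components: dict[str, list[str]] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    version: str = "1"


def sha256_file(path: Path | str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def make_identifier_url(identifier: str, base_namespace: str,
                        ledger: RegistryLedger | None = None) -> str:
    """Resolvable URL for a minted LDS/LDG identifier.

    Pure concatenation ``<namespace>/<id>``; when a ledger is supplied the
    identifier must actually be minted in it.
    """
    if ledger is not None:
        known = set(ledger.groups) | set(
            d.lds_id for g in ledger.groups.values() for d in g.datasets)
        if identifier not in known:
            raise UnregisteredReference(
                f"{identifier!r} is not a minted group/dataset identifier")
    return f"{base_namespace.rstrip('/')}/{identifier}"


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def build_package(ledger: RegistryLedger, specs: SpecRegistry, lds_id: str,
                  output_path: Path | str,
                  payload_dir: Path | str | None = None,
                  assay_metadata: Mapping[str, str] | None = None,
                  experimental_rows: list[Mapping[str, str]] | None = None,
                  pipeline_specs: Mapping[str, str] | None = None,
                  version: str = "1") -> DatasetPackage:
    """Assemble the six-component package directory for one dataset.

    Refuses to build when the dataset metadata fails the dataset
    specification, when a batch used in the dataset references an
    unregistered reagent, or when a payload file's digest disagrees with
    the checksum registered for it.
    """
    group, entry = ledger.get_dataset(lds_id)

    # dataset metadata must be clean before anything is written
    record = SubmissionRecord(family="dataset", category="Dataset",
                              center_id=group.center_id,
                              values=dict(entry.dataset_metadata))
    report = validate_record(record, specs, ledger=None)
    if not report.passed:
        raise PackagingError(
            f"dataset metadata for {lds_id} fails validation:\n"
            + report.summary())

    batches = [b for b in ledger.batches.values()
               if lds_id in b.datasets_used_in]
    for b in batches:
        if b.lincs_id not in ledger.entities:
            raise PackagingError(
                f"batch ({b.center_id},{b.batch_id}) references "
                f"unregistered reagent {b.lincs_id}")

    root = Path(output_path) / lds_id
    if root.exists():
        shutil.rmtree(root)
    (root / "data").mkdir(parents=True)
    (root / "metadata").mkdir()
    (root / "pipeline").mkdir()

    components: dict[str, list[str]] = {role: [] for role in COMPONENT_ROLES}

    # (ii) payload files, byte-identical, digest-checked against the registry
    for rel_path, expected in sorted(entry.file_refs.items()):
        src = Path(payload_dir or ".") / rel_path
        if not src.exists():
            raise PackagingError(f"payload file missing: {src}")
        actual = sha256_file(src)
        if actual != expected:
            raise PackagingError(
                f"checksum mismatch on payload {rel_path!r}: "
                f"registered {expected[:12]}..., found {actual[:12]}...")
        dst = root / "data" / Path(rel_path).name
        shutil.copyfile(src, dst)
        components["data_files"].append(f"data/{dst.name}")

    # (iii) one reagent metadata file per category used, with canonical IDs
    by_category: dict[str, list] = {}
    for b in sorted(batches, key=lambda b: (b.center_id, b.batch_id)):
        ent = ledger.entities[b.lincs_id]
        by_category.setdefault(ent.entity_kind, []).append((b, ent))
    for kind in sorted(by_category):
        category = get_category(specs, "reagent", kind)
        header = ["LINCS ID", "Canonical Key", "Center Name",
                  "Center-specific Reagent ID"] + [
                      f.name for f in category.fields
                      if f.name not in ("LINCS ID", "Center Name",
                                        "Center-specific Reagent ID")]
        rows = []
        for b, ent in by_category[kind]:
            merged = {**ent.metadata, **b.batch_metadata}
            rows.append([ent.lincs_id, ent.canonical_key, b.center_id,
                         b.batch_id] + [merged.get(h, "") for h in header[4:]])
        fname = "metadata/reagents_" + kind.lower().replace(" ", "_") + ".tsv"
        _write_tsv(root / fname, header, rows)
        components["reagent_metadata"].append(fname)

    # (iv) assay + experimental metadata (two files, one component role)
    assay_cat = get_category(specs, "assay", "Assay")
    assay_values = dict(assay_metadata or {})
    assay_values.setdefault("Assay Name", group.assay_name)
    _write_tsv(root / "metadata/assay.tsv",
               [f.name for f in assay_cat.fields],
               [[assay_values.get(f.name, "") for f in assay_cat.fields]])
    components["assay_and_experimental_metadata"].append("metadata/assay.tsv")
    exp_rows = experimental_rows or []
    exp_header = sorted({k for row in exp_rows for k in row}) or ["Experiment ID"]
    _write_tsv(root / "metadata/experimental.tsv", exp_header,
               [[row.get(h, "") for h in exp_header] for row in exp_rows])
    components["assay_and_experimental_metadata"].append(
        "metadata/experimental.tsv")

    # (v) dataset metadata, spec field order
    dataset_cat = get_category(specs, "dataset", "Dataset")
    _write_tsv(root / "metadata/dataset.tsv",
               [f.name for f in dataset_cat.fields],
               [[entry.dataset_metadata.get(f.name, "")
                 for f in dataset_cat.fields]])
    components["dataset_metadata"].append("metadata/dataset.tsv")

    # (vi) processing pipeline parameters
    pipeline = dict(pipeline_specs or {})
    pipeline.setdefault("data_level", str(entry.data_level))
    (root / "pipeline/processing_pipeline_specs.json").write_text(
        json.dumps(pipeline, indent=2, sort_keys=True) + "\n")
    components["processing_pipeline_specs"].append(
        "pipeline/processing_pipeline_specs.json")

    # (i) manifest over everything written so far
    entries = []
    checksums = {}
    for role in COMPONENT_ROLES:
        for rel in components[role]:
            f = root / rel
            digest = sha256_file(f)
            checksums[rel] = digest
            entries.append({"path": rel, "role": role, "sha256": digest,
                            "bytes": f.stat().st_size})
    manifest = {
        "lds_id": lds_id,
        "ldg_id": group.ldg_id,
        "version": version,
        "created": EPOCH_TIMESTAMP,
        "component_roles": list(COMPONENT_ROLES),
        "entries": entries,
    }
    (root / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    components["readme_manifest"].append(MANIFEST_NAME)

    return DatasetPackage(lds_id=lds_id, path=root, components=components,
                          checksums=checksums, version=version)


def verify_package(path: Path | str,
                   specs: SpecRegistry | None = None) -> ValidationReport:
    """Re-check a package on disk: digests, the six roles, metadata parse.

    A missing manifest is a hard failure (raises); everything else is
    reported as issues in a validation-style report.
    """
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise PackagingError(f"no {MANIFEST_NAME} in {root}")
    manifest = json.loads(manifest_path.read_text())
    report = ValidationReport(record_count=len(manifest.get("entries", [])))

    def issue(code: str, message: str, fld: str | None = None) -> None:
        report.issues.append(ValidationIssue(
            code=code, severity="error", message=message, field=fld))

    seen_roles = {"readme_manifest"}
    for entry in manifest.get("entries", []):
        rel, role = entry["path"], entry["role"]
        seen_roles.add(role)
        f = root / rel
        if not f.exists():
            issue("UNREGISTERED_REFERENCE", f"listed file missing: {rel}",
                  rel)
            continue
        if sha256_file(f) != entry["sha256"]:
            issue("FORMAT_ERROR", f"digest mismatch on {rel}", rel)
    missing_roles = set(COMPONENT_ROLES) - seen_roles
    for role in sorted(missing_roles):
        issue("MISSING_REQUIRED", f"component role absent: {role}", role)

    if specs is not None and not missing_roles:
        dataset_tsv = root / "metadata/dataset.tsv"
        if dataset_tsv.exists():
            rows = read_package_tsv(dataset_tsv)
            expected = get_category(specs, "dataset",
                                    "Dataset").field_names
            if rows and tuple(rows[0].keys()) != expected:
                issue("FORMAT_ERROR",
                      "dataset metadata header does not match the spec",
                      "metadata/dataset.tsv")
    return report


def read_package_tsv(path: Path | str) -> list[dict[str, str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def make_citation(ledger: RegistryLedger, lds_id: str,
                  base_namespace: str = "https://identifiers.example/lincs.data",
                  ) -> CitationRecord:
    """Citation record for a dataset, derived entirely from registry state.

    Requires PI Name, Dataset Title, Dataset Release Date, Repository,
    Resource Type and Dataset Version in the dataset metadata; missing
    sources are reported together in one error.
    """
    _, entry = ledger.get_dataset(lds_id)
    meta = entry.dataset_metadata
    needed = ("PI Name", "Dataset Title", "Dataset Release Date",
              "Repository", "Resource Type", "Dataset Version")
    gaps = [name for name in needed if not str(meta.get(name, "")).strip()]
    if gaps:
        raise PackagingError(
            f"incomplete citation for {lds_id}: missing {', '.join(gaps)}")
    release = str(meta["Dataset Release Date"]).strip()
    return CitationRecord(
        authors=str(meta["PI Name"]),
        title=str(meta["Dataset Title"]),
        year=release[:4],
        repository=str(meta["Repository"]),
        resource_type=str(meta["Resource Type"]),
        version=str(meta["Dataset Version"]),
        identifier_url=make_identifier_url(lds_id, base_namespace, ledger))
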