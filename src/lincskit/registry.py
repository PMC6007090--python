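"""The reagent and dataset registry (system of record).

The ledger stores three kinds of state:

* **canonical entities** — one record per standardized reagent, carrying a
  persistent prefixed identifier (``LSM-000001`` style). A canonical entity
  is deduplicated on a *canonical key*: the InChIKey for small molecules
  (produced by :mod:`lincskit.chem`), a normalized name/accession key for
  every other reagent kind. Registering a known key returns the existing
  identifier; identifiers are never reissued or mutated.
* **batches** — center-scoped physical samples of a canonical entity
  (vendor, lot), keyed by ``(center_id, batch_id)``, each pointing at its
  canonical record so datasets produced from different suppliers' samples
  of the same compound integrate under one identifier.
* **dataset groups and datasets** — assay-specific collections of
  experiments (LDG) whose files are split into per-data-level datasets
  (LDS). Levels 1-4 carry the fixed role vocabulary raw / processed /
  normalized / signature; higher levels are signature-like extensions.

Every mutation is appended to an event log; replaying the log rebuilds an
identical ledger, which is also how the ledger is persisted (JSON lines,
one event per line). Deletion is tombstoning: a withdrawn entity keeps its
identifier and its counter is never reused.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

from .spec_model import REAGENT_CATEGORIES, CELL_CATEGORIES

#: identifier prefix for each reagent category, plus dataset groups/datasets
REAGENT_PREFIXES: dict[str, str] = {
    "Small molecules": "LSM",
    "Cell lines": "LDC",
    "Primary cells": "LPC",
    "Embryonic stem cells": "LES",
    "Differentiated cells": "LDF",
    "iPSCs": "LIP",
    "Nucleic acids reagents": "LNA",
    "Proteins": "LPR",
    "Antibody reagents": "LAB",
    "Unclassified perturbagens": "LUP",
    "Other reagents": "LOR",
}
ID_PREFIXES: tuple[str, ...] = tuple(REAGENT_PREFIXES.values()) + ("LDG", "LDS")

#: fixed role vocabulary for data levels 1-4; levels above 4 are signatures
DATA_LEVEL_ROLES = {1: "raw", 2: "processed", 3: "normalized", 4: "signature"}


def data_level_role(level: int) -> str:
    if level < 1:
        raise RegistryError(f"data level must be >= 1, got {level}")
    return DATA_LEVEL_ROLES.get(level, "signature")


class RegistryError(ValueError):
    """Invalid registry operation (bad kind, dangling reference, conflict)."""


class UnregisteredReference(RegistryError):
    """An operation referenced an identifier absent from the ledger."""


class ProvenanceError(RegistryError):
    """An invalid parent link (self-link, cycle, or non-cell kind)."""


@dataclass
class CanonicalEntity:
    lincs_id: str
    entity_kind: str
    canonical_key: str
    metadata: dict[str, Any] = field(default_factory=dict)
    parent_id: str | None = None
    withdrawn: bool = False


@dataclass
class BatchRecord:
    batch_id: str
    lincs_id: str
    center_id: str
    batch_metadata: dict[str, Any] = field(default_factory=dict)
    datasets_used_in: list[str] = field(default_factory=list)


@dataclass
class DatasetEntry:
    lds_id: str
    data_level: int
    flavor: str | None = None
    file_refs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    dataset_metadata: dict[str, Any] = field(default_factory=dict)


@dataclass
class DatasetGroup:
    ldg_id: str
    center_id: str
    assay_name: str
    partition_rule: str = ""
    datasets: list[DatasetEntry] = field(default_factory=list)

    def dataset(self, lds_id: str) -> DatasetEntry | None:
        for d in self.datasets:
            if d.lds_id == lds_id:
                return d
        return None


class RegistryLedger:
    """Event-sourced registry state. All mutation goes through ``apply``."""

    def __init__(self, id_width: int = 6):
        self.id_width = id_width
        self.entities: dict[str, CanonicalEntity] = {}
        self.batches: dict[tuple[str, str], BatchRecord] = {}
        self.groups: dict[str, DatasetGroup] = {}
        self.id_counters: dict[str, int] = {p: 0 for p in ID_PREFIXES}
        self.events: list[dict] = []
        self._key_index: dict[tuple[str, str], str] = {}
        self._lds_index: dict[str, str] = {}  # lds_id -> ldg_id

    # -- identifier minting -------------------------------------------------

    def mint_id(self, kind: str) -> str:
        """Mint the next identifier for a prefix kind (never reused)."""
        if kind not in self.id_counters:
            raise RegistryError(
                f"unknown identifier kind {kind!r}; "
                f"known: {', '.join(ID_PREFIXES)}")
        return self._apply({"op": "mint", "kind": kind})

    # -- reagents -----------------------------------------------------------

    def register_reagent(self, entity_kind: str, canonical_key: str,
                         metadata: dict | None = None) -> str:
        """Return the identifier for a canonical key, minting one if new.

        The canonical key must already be the standardized representation
        (structure key for small molecules, normalized name key otherwise);
        an identical key registered twice maps to one canonical entity.
        """
        if entity_kind not in REAGENT_PREFIXES:
            raise RegistryError(
                f"unknown reagent kind {entity_kind!r}; must be one of the "
                f"{len(REAGENT_CATEGORIES)} reagent categories")
        if not canonical_key or not str(canonical_key).strip():
            raise RegistryError("empty canonical key")
        existing = self._key_index.get((entity_kind, canonical_key))
        if existing is not None:
            return existing
        return self._apply({"op": "register", "kind": entity_kind,
                            "key": canonical_key, "metadata": metadata or {}})

    def tombstone(self, lincs_id: str) -> None:
        """Withdraw an entity; the identifier is retained, never reissued."""
        if lincs_id not in self.entities:
            raise UnregisteredReference(f"unknown id {lincs_id!r}")
        self._apply({"op": "tombstone", "id": lincs_id})

    def record_batch(self, center_id: str, batch_id: str, lincs_id: str,
                     batch_metadata: dict | None = None) -> BatchRecord:
        """Record a center's physical sample of a canonical entity.

        Idempotent for an identical re-submission; a differing re-submission
        of the same ``(center_id, batch_id)`` is a conflict.
        """
        if lincs_id not in self.entities:
            raise UnregisteredReference(
                f"batch references unregistered id {lincs_id!r}")
        meta = batch_metadata or {}
        prior = self.batches.get((center_id, batch_id))
        if prior is not None:
            if prior.lincs_id == lincs_id and prior.batch_metadata == meta:
                return prior
            raise RegistryError(
                f"batch ({center_id!r}, {batch_id!r}) already recorded "
                f"with different content")
        self._apply({"op": "batch", "center": center_id, "batch": batch_id,
                     "id": lincs_id, "metadata": meta})
        return self.batches[(center_id, batch_id)]

    def link_batch_to_dataset(self, center_id: str, batch_id: str,
                              lds_id: str) -> None:
        if (center_id, batch_id) not in self.batches:
            raise UnregisteredReference(
                f"unknown batch ({center_id!r}, {batch_id!r})")
        if lds_id not in self._lds_index:
            raise UnregisteredReference(f"unknown dataset {lds_id!r}")
        if lds_id in self.batches[(center_id, batch_id)].datasets_used_in:
            return
        self._apply({"op": "batch_use", "center": center_id,
                     "batch": batch_id, "lds": lds_id})

    # -- cell provenance ----------------------------------------------------

    def link_cell_provenance(self, child_id: str, parent_id: str) -> None:
        """Record that a cell entity is derived from another cell entity.

        Differentiated cells derive from iPSCs, iPSCs from primary cells;
        the chain must stay acyclic so inherited metadata is well defined.
        """
        for lid in (child_id, parent_id):
            ent = self.entities.get(lid)
            if ent is None:
                raise UnregisteredReference(f"unknown id {lid!r}")
            if ent.entity_kind not in CELL_CATEGORIES:
                raise ProvenanceError(
                    f"{lid} is kind {ent.entity_kind!r}, not a cell category")
        if child_id == parent_id:
            raise ProvenanceError(f"self-link on {child_id}")
        # walk up from the proposed parent; meeting the child forms a cycle
        seen = {child_id}
        cursor: str | None = parent_id
        while cursor is not None:
            if cursor in seen:
                raise ProvenanceError(
                    f"linking {child_id} -> {parent_id} creates a cycle")
            seen.add(cursor)
            cursor = self.entities[cursor].parent_id
        self._apply({"op": "link", "child": child_id, "parent": parent_id})

    def parent_chain(self, cell_id: str) -> list[str]:
        """Identifiers from the given cell up to the root ancestor."""
        if cell_id not in self.entities:
            raise UnregisteredReference(f"unknown id {cell_id!r}")
        chain = [cell_id]
        cursor = self.entities[cell_id].parent_id
        while cursor is not None:
            chain.append(cursor)
            cursor = self.entities[cursor].parent_id
        return chain

    def resolve_inherited_metadata(self, cell_id: str) -> dict[str, Any]:
        """Merge ancestor metadata root-first; nearer records win.

        The derived cell inherits every field of its ancestors, each child
        overriding its ancestors on conflict; stored records are untouched.
        """
        merged: dict[str, Any] = {}
        for lid in reversed(self.parent_chain(cell_id)):
            merged.update(self.entities[lid].metadata)
        return merged

    # -- dataset groups and datasets ----------------------------------------

    def create_dataset_group(self, center_id: str, assay_name: str,
                             partition_rule: str = "") -> str:
        """New assay-specific collection of experiments with a fresh LDG ID.

        The partition rule (by release date, by mechanism class, ...) is
        center policy and stored verbatim.
        """
        return self._apply({"op": "group", "center": center_id,
                            "assay": assay_name, "rule": partition_rule})

    def add_dataset(self, ldg_id: str, data_level: int,
                    flavor: str | None = None,
                    file_refs: dict[str, str] | None = None,
                    dataset_metadata: dict | None = None) -> str:
        """Attach a per-data-level dataset to a group; returns its LDS ID.

        A group holds at most one dataset per (level, flavor); multiple
        datasets of one level are allowed when their flavors differ.
        """
        group = self.groups.get(ldg_id)
        if group is None:
            raise UnregisteredReference(f"unknown group {ldg_id!r}")
        data_level = int(data_level)
        data_level_role(data_level)  # validates level >= 1
        for d in group.datasets:
            if d.data_level == data_level and d.flavor == flavor:
                raise RegistryError(
                    f"group {ldg_id} already has a level-{data_level} "
                    f"dataset with flavor {flavor!r}")
        return self._apply({
            "op": "dataset", "ldg": ldg_id, "level": data_level,
            "flavor": flavor, "files": file_refs or {},
            "metadata": dataset_metadata or {}})

    def get_dataset(self, lds_id: str) -> tuple[DatasetGroup, DatasetEntry]:
        ldg_id = self._lds_index.get(lds_id)
        if ldg_id is None:
            raise UnregisteredReference(f"unknown dataset {lds_id!r}")
        group = self.groups[ldg_id]
        entry = group.dataset(lds_id)
        assert entry is not None
        return group, entry

    # -- event application --------------------------------------------------

    def _apply(self, event: dict) -> Any:
        result = self._execute(event)
        self.events.append(event)
        return result

    def _execute(self, event: dict) -> Any:
        op = event["op"]
        if op == "mint":
            return self._mint(event["kind"])
        if op == "register":
            lincs_id = self._mint(REAGENT_PREFIXES[event["kind"]])
            ent = CanonicalEntity(lincs_id=lincs_id,
                                  entity_kind=event["kind"],
                                  canonical_key=event["key"],
                                  metadata=dict(event["metadata"]))
            self.entities[lincs_id] = ent
            self._key_index[(event["kind"], event["key"])] = lincs_id
            return lincs_id
        if op == "tombstone":
            self.entities[event["id"]].withdrawn = True
            return None
        if op == "batch":
            rec = BatchRecord(batch_id=event["batch"], lincs_id=event["id"],
                              center_id=event["center"],
                              batch_metadata=dict(event["metadata"]))
            self.batches[(event["center"], event["batch"])] = rec
            return rec
        if op == "batch_use":
            self.batches[(event["center"], event["batch"])] \
                .datasets_used_in.append(event["lds"])
            return None
        if op == "link":
            self.entities[event["child"]].parent_id = event["parent"]
            return None
        if op == "group":
            ldg_id = self._mint("LDG")
            self.groups[ldg_id] = DatasetGroup(
                ldg_id=ldg_id, center_id=event["center"],
                assay_name=event["assay"], partition_rule=event["rule"])
            return ldg_id
        if op == "dataset":
            lds_id = self._mint("LDS")
            metadata = dict(event["metadata"])
            # stamp the minted identifiers into the stored dataset record
            metadata["Dataset Identifier"] = lds_id
            metadata["Dataset Group Identifier"] = event["ldg"]
            entry = DatasetEntry(lds_id=lds_id, data_level=event["level"],
                                 flavor=event["flavor"],
                                 file_refs=dict(event["files"]),
                                 dataset_metadata=metadata)
            self.groups[event["ldg"]].datasets.append(entry)
            self._lds_index[lds_id] = event["ldg"]
            return lds_id
        raise RegistryError(f"unknown event op {op!r}")

    def _mint(self, prefix: str) -> str:
        self.id_counters[prefix] += 1
        return f"{prefix}-{self.id_counters[prefix]:0{self.id_width}d}"

    # -- integrity and persistence ------------------------------------------

    def check_integrity(self) -> list[str]:
        """Full referential scan; returns human-readable problems."""
        problems = []
        for (center, batch), rec in self.batches.items():
            if rec.lincs_id not in self.entities:
                problems.append(f"batch ({center},{batch}) -> missing "
                                f"{rec.lincs_id}")
            for lds in rec.datasets_used_in:
                if lds not in self._lds_index:
                    problems.append(f"batch ({center},{batch}) used in "
                                    f"missing dataset {lds}")
        for lid, ent in self.entities.items():
            if ent.parent_id is not None and ent.parent_id not in self.entities:
                problems.append(f"{lid} -> missing parent {ent.parent_id}")
        return problems

    def to_jsonl(self, path: Path | str) -> None:
        """Persist as one JSON event per line (replayable audit log)."""
        lines = [json.dumps({"op": "init", "id_width": self.id_width})]
        lines += [json.dumps(e, sort_keys=True) for e in self.events]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_jsonl(cls, path: Path | str) -> "RegistryLedger":
        ledger: RegistryLedger | None = None
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            event = json.loads(line)
            if event["op"] == "init":
                ledger = cls(id_width=event.get("id_width", 6))
            else:
                if ledger is None:
                    raise RegistryError("event log missing init line")
                ledger._apply(event)
        if ledger is None:
            raise RegistryError("empty event log")
        return ledger

    @classmethod
    def replay(cls, events: Iterable[dict], id_width: int = 6) -> "RegistryLedger":
        ledger = cls(id_width=id_width)
        for event in events:
            ledger._apply(event)
        return ledger

    def to_sqlite(self, path: Path | str) -> None:
        """Materialize the ledger into an embedded relational store.

        The event log is kept verbatim in a key-value table (the source of
        truth for reload); entities, batches, groups and datasets are also
        written as relational tables for ad-hoc querying.
        """
        con = sqlite3.connect(str(path))
        try:
            cur = con.cursor()
            cur.executescript("""
                DROP TABLE IF EXISTS events;
                DROP TABLE IF EXISTS entities;
                DROP TABLE IF EXISTS batches;
                DROP TABLE IF EXISTS dataset_groups;
                DROP TABLE IF EXISTS datasets;
                CREATE TABLE events (seq INTEGER PRIMARY KEY, event TEXT);
                CREATE TABLE entities (lincs_id TEXT PRIMARY KEY,
                    entity_kind TEXT, canonical_key TEXT, metadata TEXT,
                    parent_id TEXT, withdrawn INTEGER);
                CREATE TABLE batches (center_id TEXT, batch_id TEXT,
                    lincs_id TEXT, batch_metadata TEXT, datasets_used_in TEXT,
                    PRIMARY KEY (center_id, batch_id));
                CREATE TABLE dataset_groups (ldg_id TEXT PRIMARY KEY,
                    center_id TEXT, assay_name TEXT, partition_rule TEXT);
                CREATE TABLE datasets (lds_id TEXT PRIMARY KEY, ldg_id TEXT,
                    data_level INTEGER, flavor TEXT, file_refs TEXT,
                    dataset_metadata TEXT);
            """)
            cur.execute("INSERT INTO events VALUES (0, ?)",
                        (json.dumps({"op": "init", "id_width": self.id_width}),))
            cur.executemany(
                "INSERT INTO events VALUES (?, ?)",
                [(i + 1, json.dumps(e, sort_keys=True))
                 for i, e in enumerate(self.events)])
            for ent in self.entities.values():
                cur.execute("INSERT INTO entities VALUES (?,?,?,?,?,?)",
                            (ent.lincs_id, ent.entity_kind, ent.canonical_key,
                             json.dumps(ent.metadata, sort_keys=True),
                             ent.parent_id, int(ent.withdrawn)))
            for rec in self.batches.values():
                cur.execute("INSERT INTO batches VALUES (?,?,?,?,?)",
                            (rec.center_id, rec.batch_id, rec.lincs_id,
                             json.dumps(rec.batch_metadata, sort_keys=True),
                             json.dumps(rec.datasets_used_in)))
            for grp in self.groups.values():
                cur.execute("INSERT INTO dataset_groups VALUES (?,?,?,?)",
                            (grp.ldg_id, grp.center_id, grp.assay_name,
                             grp.partition_rule))
                for d in grp.datasets:
                    cur.execute("INSERT INTO datasets VALUES (?,?,?,?,?,?)",
                                (d.lds_id, grp.ldg_id, d.data_level, d.flavor,
                                 json.dumps(d.file_refs, sort_keys=True),
                                 json.dumps(d.dataset_metadata,
                                            sort_keys=True)))
            con.commit()
        finally:
            con.close()

    @classmethod
    def from_sqlite(cls, path: Path | str) -> "RegistryLedger":
        con = sqlite3.connect(str(path))
        try:
            rows = con.execute(
                "SELECT event FROM events ORDER BY seq").fetchall()
        finally:
            con.close()
        if not rows:
            raise RegistryError("empty event table")
        init = json.loads(rows[0][0])
        ledger = cls(id_width=init.get("id_width", 6))
        for (raw,) in rows[1:]:
            ledger._apply(json.loads(raw))
        return ledger
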