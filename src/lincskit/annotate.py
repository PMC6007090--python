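"""Bioactivity curation/aggregation and offline cross-reference mapping.

Curation of a ChEMBL-style bioactivity table follows four fixed steps:

1. **Filter** — keep a record iff confidence score >= 5, assay type is
   binding or functional, the endpoint is one of the seven accepted result
   types (Potency, IC50, Kd, Ki, Activity, EC50, AC50) and the measurement
   comes from concentration-response data. Every rejection logs the first
   failing criterion.
2. **p-transform** — convert the activity concentration to molar and take
   -log10 (a pChEMBL-style value): 1 uM -> 6.0, 10 nM -> 8.0.
3. **Aggregate** — group by (compound LSM ID, target ID, endpoint) and
   average the p-values; one output row per group with the member count.
4. **Annotate** — assign each target a gene symbol from a UniProt lookup
   and attach external compound identifiers from per-source resolvers.

Resolvers are pure offline lookup tables (canonical structure key ->
external IDs), standing in for the web services (UniChem, PubChem PUG,
UniProt) the production system queries; an unknown key yields an empty
result, never an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: accepted endpoints, canonical form (matching is case- and
#: subscript-insensitive: "IC_50" == "ic50" == "IC50")
ACCEPTED_ENDPOINTS = ("Potency", "IC50", "Kd", "Ki", "Activity",
                      "EC50", "AC50")

ACCEPTED_ASSAY_TYPES = frozenset({"binding", "functional"})

MIN_CONFIDENCE = 5

#: molar conversion factors; exact decade factors only
UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
}


def normalize_endpoint(label: str) -> str | None:
    """Canonical endpoint label, or None if not an accepted result type."""
    folded = str(label).replace("_", "").replace(" ", "").lower()
    for canonical in ACCEPTED_ENDPOINTS:
        if folded == canonical.lower():
            return canonical
    return None


@dataclass(frozen=True)
class ActivityRecord:
    compound_key: str            # InChIKey or LSM ID
    target_id: str               # e.g. ChEMBL target identifier
    target_accession: str        # protein accession (UniProt)
    endpoint: str
    value: float                 # activity concentration (> 0)
    units: str
    confidence: int
    assay_type: str
    is_concentration_response: bool = True
    relation: str = "="          # censored (>, <) records do not aggregate
    p_value: float | None = None  # filled by p-transform


@dataclass(frozen=True)
class AggregatedActivity:
    lsm_id: str
    target_id: str
    endpoint: str
    p_value_mean: float
    n_records: int
    gene_symbol: str | None = None


@dataclass
class RejectionLog:
    """Per-record rejections with the first failing criterion."""

    entries: list[tuple[ActivityRecord, str]] = field(default_factory=list)

    def add(self, record: ActivityRecord, reason: str) -> None:
        self.entries.append((record, reason))

    def reasons(self) -> list[str]:
        return [reason for _, reason in self.entries]


def filter_activities(records: Iterable[ActivityRecord],
                      include_censored: bool = False,
                      ) -> tuple[list[ActivityRecord], RejectionLog]:
    """Apply the curation criteria; criteria are checked in a fixed order
    (confidence, assay type, endpoint, concentration-response, relation)
    and the first failure is logged."""
    retained, log = [], RejectionLog()
    for rec in records:
        if rec.confidence < MIN_CONFIDENCE:
            log.add(rec, "confidence")
            continue
        if str(rec.assay_type).lower() not in ACCEPTED_ASSAY_TYPES:
            log.add(rec, "assay_type")
            continue
        canonical = normalize_endpoint(rec.endpoint)
        if canonical is None:
            log.add(rec, "endpoint")
            continue
        if not rec.is_concentration_response:
            log.add(rec, "concentration_response")
            continue
        if rec.relation != "=" and not include_censored:
            log.add(rec, "censored_relation")
            continue
        retained.append(replace(rec, endpoint=canonical))
    return retained, log


def p_transform(value: float, units: str) -> float:
    """-log10 of the activity value expressed in molar."""
    factor = UNIT_FACTORS.get(str(units).strip())
    if factor is None:
        raise ValueError(f"unknown concentration unit {units!r}")
    value = float(value)
    if value <= 0:
        raise ValueError(f"nonpositive activity value {value!r}")
    return -math.log10(value * factor)


def p_transform_records(records: Iterable[ActivityRecord],
                        ) -> tuple[list[ActivityRecord], RejectionLog]:
    """Attach p-values; unconvertible records are logged, not raised."""
    out, log = [], RejectionLog()
    for rec in records:
        try:
            out.append(replace(rec, p_value=p_transform(rec.value, rec.units)))
        except ValueError as exc:
            log.add(rec, f"p_transform: {exc}")
    return out, log


def aggregate_activities(records: Sequence[ActivityRecord],
                         compound_to_lsm: Mapping[str, str] | None = None,
                         symbol_resolver: "XrefResolver | None" = None,
                         ) -> tuple[list[AggregatedActivity], RejectionLog]:
    """One aggregate per (LSM ID, target, endpoint), mean of member p-values.

    ``compound_to_lsm`` maps submitted compound keys (InChIKeys or batch
    keys) onto canonical LSM IDs; a record whose compound cannot be mapped
    is logged and skipped. Records must already carry p-values. Output is
    sorted by the group key, so aggregation is invariant under input order.
    """
    log = RejectionLog()
    groups: dict[tuple[str, str, str], list[float]] = {}
    accessions: dict[tuple[str, str, str], str] = {}
    for rec in records:
        if rec.p_value is None:
            log.add(rec, "missing p-value (run p_transform_records first)")
            continue
        if compound_to_lsm is not None:
            lsm = compound_to_lsm.get(rec.compound_key)
            if lsm is None:
                log.add(rec, "unmapped_compound")
                continue
        else:
            lsm = rec.compound_key
        key = (lsm, rec.target_id, rec.endpoint)
        groups.setdefault(key, []).append(rec.p_value)
        accessions.setdefault(key, rec.target_accession)
    out = []
    for key in sorted(groups):
        lsm, target_id, endpoint = key
        values = groups[key]
        symbol = None
        if symbol_resolver is not None:
            symbol = map_target_symbol(accessions[key], symbol_resolver)
        # sorted summation: the mean is bit-identical under input shuffles
        mean = math.fsum(sorted(values)) / len(values)
        out.append(AggregatedActivity(
            lsm_id=lsm, target_id=target_id, endpoint=endpoint,
            p_value_mean=mean, n_records=len(values),
            gene_symbol=symbol))
    return out, log


# -- offline cross-reference resolvers --------------------------------------

KNOWN_SOURCES = ("PubChem", "ChEMBL", "ChEBI", "DrugCentral", "PDB",
                 "BindingDB", "UniProt", "Cellosaurus", "CLO")


@dataclass
class XrefResolver:
    """A pure offline lookup table for one external source."""

    source_name: str
    table: dict[str, tuple[str, ...]] = field(default_factory=dict)
    source_version: str = "22"
    missing_log: list[str] = field(default_factory=list)

    def lookup(self, key: str) -> tuple[str, ...]:
        hit = self.table.get(key)
        if hit is None:
            self.missing_log.append(key)
            return ()
        return hit

    @classmethod
    def from_tsv(cls, source_name: str, path: Path | str,
                 source_version: str = "22") -> "XrefResolver":
        """Two-column TSV: canonical key, external ID (repeats allowed)."""
        table: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, ext = line.partition("\t")
            table.setdefault(key.strip(), []).append(ext.strip())
        return cls(source_name=source_name,
                   table={k: tuple(v) for k, v in table.items()},
                   source_version=source_version)

    def to_tsv(self, path: Path | str) -> None:
        lines = [f"{k}\t{e}" for k in sorted(self.table)
                 for e in self.table[k]]
        Path(path).write_text("\n".join(lines) + "\n")


def map_target_symbol(accession: str,
                      resolver: XrefResolver) -> str | None:
    """Gene symbol for a protein accession, or None (accession logged)."""
    hits = resolver.lookup(accession)
    return hits[0] if hits else None


@dataclass(frozen=True)
class XrefConflict:
    source_name: str
    canonical_key: str
    submitted: str
    resolved: tuple[str, ...]


def resolve_xrefs(canonical_key: str, resolvers: Sequence[XrefResolver],
                  submitted: Mapping[str, str] | None = None,
                  ) -> tuple[dict[str, tuple[str, ...]], list[XrefConflict]]:
    """Query every configured resolver for one canonical structure key.

    The result carries an entry per source (possibly empty). When a center
    submitted its own external ID for a source and the resolver disagrees,
    the pair is surfaced as a conflict — the submitted value is never
    silently overwritten.
    """
    mapping: dict[str, tuple[str, ...]] = {}
    conflicts: list[XrefConflict] = []
    for resolver in resolvers:
        hits = resolver.lookup(canonical_key)
        mapping[resolver.source_name] = hits
        if submitted and resolver.source_name in submitted:
            center_value = str(submitted[resolver.source_name])
            if hits and center_value not in hits:
                conflicts.append(XrefConflict(
                    source_name=resolver.source_name,
                    canonical_key=canonical_key,
                    submitted=center_value, resolved=hits))
    return mapping, conflicts


# -- table I/O ---------------------------------------------------------------

ACTIVITY_COLUMNS = ("compound_key", "target_id", "target_accession",
                    "endpoint", "value", "units", "confidence", "assay_type",
                    "is_concentration_response", "relation")


def read_activity_table(path: Path | str) -> list[ActivityRecord]:
    """TSV with the declared activity columns in the header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ACTIVITY_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    out = []
    for row in df.to_dict(orient="records"):
        out.append(ActivityRecord(
            compound_key=row["compound_key"],
            target_id=row["target_id"],
            target_accession=row["target_accession"],
            endpoint=row["endpoint"],
            value=float(row["value"]),
            units=row["units"],
            confidence=int(row["confidence"]),
            assay_type=row["assay_type"],
            is_concentration_response=str(
                row.get("is_concentration_response", "true")
            ).lower() in ("1", "true", "yes"),
            relation=row.get("relation", "=") or "="))
    return out


def write_aggregated_table(aggregates: Sequence[AggregatedActivity],
                           path: Path | str,
                           source_version: str = "22") -> None:
    lines = ["# source_version: " + source_version,
             "lsm_id\ttarget_id\tgene_symbol\tendpoint\tp_value_mean\tn_records"]
    for a in aggregates:
        lines.append("\t".join([
            a.lsm_id, a.target_id, a.gene_symbol or "",
            a.endpoint, f"{a.p_value_mean:.12g}", str(a.n_records)]))
    Path(path).write_text("\n".join(lines) + "\n")
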