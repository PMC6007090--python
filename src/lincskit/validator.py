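"""Submission validation against the metadata specifications.

A center submission is a table (CSV/TSV with a header of field labels, or
a JSON array of records) targeting one (family, category). Validation
checks, per record:

* completeness — every importance-1 field present and non-empty (an
  explicit "not applicable" sentinel counts as provided); importance-2
  omissions are warnings only;
* vocabulary — values of vocabulary fields must match the named term list
  exactly after whitespace trimming and Unicode NFC normalization;
* typing — integer / decimal / date / url values must parse;
* reference integrity — fields that reference registered reagents must
  resolve in the ledger;
* unknown fields — keys outside the category's field list are flagged.

A report passes iff it carries no error-severity issue; warnings survive
in the report for the manual-review checkpoint to acknowledge.
"""

from __future__ import annotations

import datetime as _dt
import unicodedata
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .spec_model import CategorySpec, SpecRegistry, get_category
from .registry import RegistryLedger

#: value accepted for a required field that genuinely does not apply
NOT_APPLICABLE = "N/A"

ISSUE_CODES = ("FORMAT_ERROR", "MISSING_REQUIRED", "MISSING_RECOMMENDED",
               "UNKNOWN_FIELD", "BAD_VOCABULARY_TERM",
               "UNREGISTERED_REFERENCE", "TYPE_MISMATCH")

#: field labels treated as references to previously registered reagents
REFERENCE_FIELDS = frozenset({"Parent Cell ID", "LINCS ID",
                              "Reagent Batch ID"})


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: str  # "error" | "warning"
    message: str
    field: str | None = None
    record_index: int | None = None

    def __post_init__(self) -> None:
        if self.code not in ISSUE_CODES:
            raise ValueError(f"unknown issue code {self.code!r}")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"bad severity {self.severity!r}")


@dataclass
class ValidationReport:
    record_count: int = 0
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def to_dict(self) -> dict:
        return {
            "record_count": self.record_count,
            "passed": self.passed,
            "issues": [
                {"code": i.code, "severity": i.severity, "field": i.field,
                 "record_index": i.record_index, "message": i.message}
                for i in self.issues
            ],
        }

    def summary(self) -> str:
        lines = [f"{self.record_count} record(s): "
                 f"{'PASS' if self.passed else 'FAIL'} "
                 f"({len(self.errors)} error(s), "
                 f"{len(self.warnings)} warning(s))"]
        for i in self.issues:
            where = f"record {i.record_index}, " if i.record_index else ""
            fld = f"field {i.field!r}: " if i.field else ""
            lines.append(f"  [{i.severity}] {i.code} {where}{fld}{i.message}")
        return "\n".join(lines)


@dataclass
class SubmissionRecord:
    family: str
    category: str
    center_id: str
    values: dict[str, Any]
    batch_id: str | None = None


@dataclass
class FieldMapping:
    """Center-specific field labels mapped to official spec labels."""

    center_id: str
    aliases: dict[str, str] = field(default_factory=dict)


class MappingConfigError(ValueError):
    """An alias targets a field absent from the target category."""


def map_center_fields(raw: Mapping[str, Any], mapping: FieldMapping,
                      category: CategorySpec,
                      batch_id: str | None = None) -> SubmissionRecord:
    """Rename center-specific keys to official labels.

    Unaliased keys already matching official labels pass through; keys that
    are neither aliased nor official are retained so validation can flag
    them as UNKNOWN_FIELD rather than dropping data silently.
    """
    official = set(category.field_names)
    for src, dst in mapping.aliases.items():
        if dst not in official:
            raise MappingConfigError(
                f"alias {src!r} -> {dst!r}: no such field in "
                f"{category.category_name!r}")
    values = {mapping.aliases.get(k, k): v for k, v in raw.items()}
    return SubmissionRecord(family=category.family,
                            category=category.category_name,
                            center_id=mapping.center_id, values=values,
                            batch_id=batch_id)


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    s = str(value).strip()
    return s == ""


def _nfc(value: Any) -> str:
    return unicodedata.normalize("NFC", str(value).strip())


def _type_ok(value: Any, kind: str) -> bool:
    s = str(value).strip()
    if s == NOT_APPLICABLE:
        return True
    if kind == "integer":
        try:
            int(s)
            return True
        except ValueError:
            return False
    if kind == "decimal":
        try:
            float(s)
            return True
        except ValueError:
            return False
    if kind == "date":
        for fmt in ("%Y-%m-%d", "%Y/%m/%d", "%Y-%m", "%Y"):
            try:
                _dt.datetime.strptime(s, fmt)
                return True
            except ValueError:
                continue
        return False
    if kind == "url":
        return s.startswith(("http://", "https://", "ftp://"))
    return True  # text / identifier / vocabulary handled separately


def validate_record(record: SubmissionRecord, registry: SpecRegistry,
                    ledger: RegistryLedger | None = None,
                    record_index: int | None = None) -> ValidationReport:
    """Check one submission record against its category specification.

    Raises :class:`~lincskit.spec_model.CategoryNotFound` when the record's
    category does not resolve — an unresolvable category is a submission
    routing problem, not a field-level finding.
    """
    category = get_category(registry, record.family, record.category)
    report = ValidationReport(record_count=1)

    def issue(code: str, severity: str, message: str,
              fld: str | None = None) -> None:
        report.issues.append(ValidationIssue(
            code=code, severity=severity, message=message, field=fld,
            record_index=record_index))

    known = {f.name: f for f in category.fields}
    for key in record.values:
        if key not in known:
            issue("UNKNOWN_FIELD", "warning",
                  f"not a field of {category.category_name!r}", key)

    for spec in category.fields:
        raw = record.values.get(spec.name)
        missing = _is_missing(raw)
        if missing:
            if spec.importance == 1:
                issue("MISSING_REQUIRED", "error",
                      "required field absent or empty", spec.name)
            elif spec.importance == 2:
                issue("MISSING_RECOMMENDED", "warning",
                      "recommended field absent or empty", spec.name)
            continue
        if str(raw).strip() == NOT_APPLICABLE:
            continue
        if spec.value_kind == "vocabulary":
            assert spec.vocabulary_ref is not None
            if not registry.term_matches(spec.vocabulary_ref, raw):
                issue("BAD_VOCABULARY_TERM", "error",
                      f"{_nfc(raw)!r} not in vocabulary "
                      f"{spec.vocabulary_ref!r}", spec.name)
        elif not _type_ok(raw, spec.value_kind):
            issue("TYPE_MISMATCH", "error",
                  f"{raw!r} is not a valid {spec.value_kind}", spec.name)
        if (ledger is not None and spec.name in REFERENCE_FIELDS
                and spec.name != "Reagent Batch ID"):
            if str(raw).strip() not in ledger.entities:
                issue("UNREGISTERED_REFERENCE", "error",
                      f"{raw!r} is not a registered reagent", spec.name)

    # batch references: the named (center, batch) sample must be registered
    if ledger is not None:
        ref = record.values.get("Reagent Batch ID")
        if ref is not None and not _is_missing(ref) \
                and str(ref).strip() != NOT_APPLICABLE:
            if (record.center_id, str(ref).strip()) not in ledger.batches:
                issue("UNREGISTERED_REFERENCE", "error",
                      f"batch {ref!r} of center {record.center_id!r} "
                      f"is not registered", "Reagent Batch ID")
    return report


def validate_table(records: Iterable[SubmissionRecord],
                   registry: SpecRegistry,
                   ledger: RegistryLedger | None = None) -> ValidationReport:
    """Validate a whole submission; issue indices are 1-based record numbers."""
    records = list(records)
    report = ValidationReport(record_count=len(records))
    if not records:
        report.issues.append(ValidationIssue(
            code="FORMAT_ERROR", severity="warning",
            message="empty submission: nothing to validate"))
        return report
    for idx, record in enumerate(records, start=1):
        sub = validate_record(record, registry, ledger, record_index=idx)
        report.issues.extend(sub.issues)
    return report


# -- file dialects ----------------------------------------------------------

def read_submission_table(path, family: str, category: str, center_id: str,
                          mapping: FieldMapping | None = None,
                          registry: SpecRegistry | None = None,
                          ) -> list[SubmissionRecord]:
    """Read CSV/TSV (header = field labels) or a JSON array of records."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise ValueError(f"{path.name}: expected a JSON array of records")
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        rows = df.to_dict(orient="records")
    out = []
    for row in rows:
        if mapping is not None:
            if registry is None:
                raise ValueError("field mapping requires a loaded registry")
            cat = get_category(registry, family, category)
            rec = map_center_fields(row, mapping, cat,
                                    batch_id=row.get("Center-specific Reagent ID"))
        else:
            rec = SubmissionRecord(family=family, category=category,
                                   center_id=center_id, values=dict(row),
                                   batch_id=row.get("Center-specific Reagent ID"))
        out.append(rec)
    return out
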