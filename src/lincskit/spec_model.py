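"""Machine-readable metadata specifications.

The toolkit ships four specification families as data files, one YAML
document per family:

* ``reagent`` — 11 categories describing the identity of every reagent
  class used in the experiments (small molecules, five cell categories,
  nucleic acids, proteins, antibodies, and two catch-all classes);
* ``experimental`` — 6 categories describing the conditions under which a
  reagent is applied (the five cell reagent categories share the single
  experimental category *Cells*);
* ``assay`` — a common core of reagent-independent assay descriptors plus
  named per-assay extension categories;
* ``dataset`` — a single category of exactly 37 non-experimental
  descriptors for attribution and release of a dataset.

Every field carries an importance tier: 1 = required, 2 = recommended,
3 = optional. Fields whose values come from a controlled vocabulary name a
flat term list shipped next to the spec files.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

FAMILIES = ("reagent", "experimental", "assay", "dataset")

#: importance tiers: 1 = required, 2 = recommended, 3 = optional
IMPORTANCE_TIERS = (1, 2, 3)

VALUE_KINDS = ("text", "integer", "decimal", "date", "vocabulary",
               "identifier", "url")

#: the eleven reagent categories, in specification order
REAGENT_CATEGORIES = (
    "Small molecules", "Cell lines", "Primary cells", "Embryonic stem cells",
    "Differentiated cells", "iPSCs", "Nucleic acids reagents", "Proteins",
    "Antibody reagents", "Unclassified perturbagens", "Other reagents",
)

#: the six experimental categories; all cell reagent categories map to "Cells"
EXPERIMENTAL_CATEGORIES = (
    "Small molecules", "Cells", "Proteins", "Antibody reagents",
    "Nucleic acid reagents", "Unclassified perturbagens",
)

#: reagent categories that denote cell model systems
CELL_CATEGORIES = frozenset({
    "Cell lines", "Primary cells", "Embryonic stem cells",
    "Differentiated cells", "iPSCs",
})


class SpecError(ValueError):
    """A bundled or user-supplied specification file is malformed."""


class CategoryNotFound(KeyError):
    """Lookup of an unknown (family, category) pair."""

    def __init__(self, family: str, name: str, valid: Iterable[str]):
        self.family = family
        self.name = name
        self.valid = sorted(valid)
        super().__init__(
            f"no category {name!r} in family {family!r}; "
            f"valid names: {', '.join(self.valid)}"
        )


@dataclass(frozen=True)
class FieldSpec:
    """One controlled metadata field."""

    name: str
    importance: int
    scope: str  # "common" (shared across categories) or "custom"
    value_kind: str
    vocabulary_ref: str | None = None
    description: str = ""
    provenance: str = "implementer-defined"

    def __post_init__(self) -> None:
        if self.importance not in IMPORTANCE_TIERS:
            raise SpecError(
                f"field {self.name!r}: importance must be 1, 2 or 3, "
                f"got {self.importance!r}")
        if self.scope not in ("common", "custom"):
            raise SpecError(f"field {self.name!r}: bad scope {self.scope!r}")
        if self.value_kind not in VALUE_KINDS:
            raise SpecError(
                f"field {self.name!r}: bad value_kind {self.value_kind!r}")
        if self.value_kind == "vocabulary" and not self.vocabulary_ref:
            raise SpecError(
                f"field {self.name!r}: vocabulary fields need vocabulary_ref")


@dataclass(frozen=True)
class CategorySpec:
    """An ordered collection of fields for one metadata category."""

    family: str
    category_name: str
    fields: tuple[FieldSpec, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SpecError(
                f"category {self.category_name!r}: duplicate fields {dupes}")

    def field_by_name(self, name: str) -> FieldSpec | None:
        for f in self.fields:
            if f.name == name:
                return f
        return None

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)


@dataclass
class SpecRegistry:
    """All loaded categories plus their controlled-term lists."""

    categories: dict[tuple[str, str], CategorySpec] = field(default_factory=dict)
    vocabularies: dict[str, tuple[str, ...]] = field(default_factory=dict)
    version: str = "1.0"

    def category_names(self, family: str) -> tuple[str, ...]:
        return tuple(name for fam, name in self.categories if fam == family)

    def vocabulary_terms(self, ref: str) -> tuple[str, ...]:
        try:
            return self.vocabularies[ref]
        except KeyError:
            raise SpecError(f"unknown vocabulary {ref!r}") from None

    def term_matches(self, ref: str, value: str) -> bool:
        """Exact match after whitespace trimming and Unicode NFC folding."""
        norm = unicodedata.normalize("NFC", str(value).strip())
        return norm in {unicodedata.normalize("NFC", t)
                        for t in self.vocabulary_terms(ref)}


def _parse_field(raw: Mapping, scope: str, context: str) -> FieldSpec:
    try:
        return FieldSpec(
            name=str(raw["name"]),
            importance=int(raw["importance"]),
            scope=scope,
            value_kind=str(raw["value_kind"]),
            vocabulary_ref=raw.get("vocabulary_ref"),
            description=str(raw.get("description", "")),
            provenance=str(raw.get("provenance", "implementer-defined")),
        )
    except (KeyError, TypeError, SpecError) as exc:
        raise SpecError(f"in {context}: {exc}") from exc


def load_family(path: Path | str) -> list[CategorySpec]:
    """Parse one family document into its categories.

    Common fields are prepended to every category of the family, so a
    category's ``fields`` is always the full ordered list a submission is
    checked against.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict) or "family" not in doc:
        raise SpecError(f"{path.name}: not a specification document")
    family = doc["family"]
    if family not in FAMILIES:
        raise SpecError(f"{path.name}: unknown family {family!r}")
    common = tuple(
        _parse_field(f, "common", f"{family} common fields")
        for f in doc.get("common_fields") or ()
    )
    out: list[CategorySpec] = []
    for cat in doc.get("categories") or ():
        name = cat.get("name")
        if not name:
            raise SpecError(f"{path.name}: category without a name")
        custom = tuple(
            _parse_field(f, "custom", f"{family}/{name}")
            for f in cat.get("fields") or ()
        )
        out.append(CategorySpec(family=family, category_name=str(name),
                                fields=common + custom))
    return out


def load_vocabulary(path: Path | str) -> tuple[str, ...]:
    """One term per line; blank lines and ``#`` comments ignored."""
    terms = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.append(line)
    return tuple(terms)


def load_specs(spec_dir: Path | str, vocab_dir: Path | str | None = None,
               version: str = "1.0") -> SpecRegistry:
    """Load a registry from a directory of family YAML files."""
    spec_dir = Path(spec_dir)
    registry = SpecRegistry(version=version)
    for path in sorted(spec_dir.glob("*.yaml")):
        for cat in load_family(path):
            key = (cat.family, cat.category_name)
            if key in registry.categories:
                raise SpecError(f"duplicate category {key}")
            registry.categories[key] = cat
    if vocab_dir is not None:
        for path in sorted(Path(vocab_dir).glob("*.txt")):
            registry.vocabularies[path.stem] = load_vocabulary(path)
    _check_builtin_counts(registry)
    return registry


def _check_builtin_counts(registry: SpecRegistry) -> None:
    for cat in registry.categories.values():
        for f in cat.fields:
            if f.value_kind == "vocabulary" and \
                    f.vocabulary_ref not in registry.vocabularies:
                raise SpecError(
                    f"category {cat.category_name!r}: field {f.name!r} "
                    f"references unknown vocabulary {f.vocabulary_ref!r}")


def load_builtin_specs() -> SpecRegistry:
    """Load the specifications bundled with the package.

    The bundle is checked on load: 11 reagent categories, 6 experimental
    categories, and a single 37-field dataset category; a deviation is a
    packaging defect and raises :class:`SpecError` naming the family.
    """
    root = resources.files("lincskit") / "data"
    registry = load_specs(Path(str(root / "specs")),
                          Path(str(root / "vocabularies")))
    reagent = registry.category_names("reagent")
    if tuple(reagent) != REAGENT_CATEGORIES:
        raise SpecError(f"reagent family: expected the 11 canonical "
                        f"categories, found {reagent}")
    experimental = registry.category_names("experimental")
    if tuple(experimental) != EXPERIMENTAL_CATEGORIES:
        raise SpecError(f"experimental family: expected the 6 canonical "
                        f"categories, found {experimental}")
    dataset = registry.category_names("dataset")
    if dataset != ("Dataset",):
        raise SpecError(f"dataset family: expected single category, "
                        f"found {dataset}")
    n = len(registry.categories[("dataset", "Dataset")].fields)
    if n != 37:
        raise SpecError(f"dataset category: expected 37 fields, found {n}")
    return registry


def get_category(registry: SpecRegistry, family: str, name: str) -> CategorySpec:
    """Case-sensitive lookup of one category."""
    try:
        return registry.categories[(family, name)]
    except KeyError:
        raise CategoryNotFound(
            family, name, registry.category_names(family)) from None


def required_fields(category: CategorySpec) -> tuple[FieldSpec, ...]:
    """Fields with importance 1, in specification order."""
    return tuple(f for f in category.fields if f.importance == 1)


def fields_by_importance(category: CategorySpec,
                         importance: int) -> tuple[FieldSpec, ...]:
    return tuple(f for f in category.fields if f.importance == importance)


def dump_specs(registry: SpecRegistry, spec_dir: Path | str,
               vocab_dir: Path | str) -> None:
    """Serialize a registry back to its on-disk form (round-trippable)."""
    spec_dir, vocab_dir = Path(spec_dir), Path(vocab_dir)
    spec_dir.mkdir(parents=True, exist_ok=True)
    vocab_dir.mkdir(parents=True, exist_ok=True)
    by_family: dict[str, list[CategorySpec]] = {}
    for (fam, _), cat in registry.categories.items():
        by_family.setdefault(fam, []).append(cat)
    for fam, cats in by_family.items():
        # factor the common prefix back out so the dumped file mirrors input
        common = [f for f in cats[0].fields if f.scope == "common"]
        doc = {
            "family": fam,
            "version": registry.version,
            "common_fields": [_field_to_dict(f) for f in common],
            "categories": [
                {"name": c.category_name,
                 "fields": [_field_to_dict(f) for f in c.fields
                            if f.scope == "custom"]}
                for c in cats
            ],
        }
        (spec_dir / f"{fam}.yaml").write_text(
            yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))
    for ref, terms in registry.vocabularies.items():
        (vocab_dir / f"{ref}.txt").write_text("\n".join(terms) + "\n")


def _field_to_dict(f: FieldSpec) -> dict:
    d = {"name": f.name, "importance": f.importance,
         "value_kind": f.value_kind}
    if f.vocabulary_ref:
        d["vocabulary_ref"] = f.vocabulary_ref
    if f.description:
        d["description"] = f.description
    d["provenance"] = f.provenance
    return d
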