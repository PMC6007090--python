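"""Small-molecule structure standardization.

Different centers submit the same compound as different physical samples —
free base vs. hydrochloride salt, drawn protonated or deprotonated, in a
different tautomeric form. Registration must consolidate all of these onto
one canonical record, so structures pass through a fixed rule sequence:

    parse -> strip_salts -> neutralize -> tautomer -> canonicalize

1. *Salt/addend stripping*: fragments matching an editable list of
   predefined counterions and solvates are removed (multi-fragment inputs
   only; a single-fragment structure is returned unchanged).
2. *Charge neutralization*: deprotonated acids gain a proton, protonated
   bases lose one; permanent charges (e.g. quaternary nitrogen) are kept
   and flagged.
3. *Canonical tautomer*: a deterministic, chemically reasonable tautomer
   is chosen (RDKit's canonical tautomer), making the pipeline idempotent
   across drawn tautomers.
4. *Canonicalization*: canonical SMILES plus standard InChI/InChIKey.

The InChIKey of the standardized structure is the canonical key used for
registration and external cross-referencing. Every checkpoint failure
produces an exception-queue entry naming the failing step — never a silent
pass-through; resolved entries re-enter the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")  # parse failures are reported as exceptions

STEPS = ("parse", "strip_salts", "neutralize", "tautomer", "canonicalize")


class StandardizationRefused(ValueError):
    """Requested a canonical key from a record that is not status=ok."""


@dataclass
class StructureRecord:
    raw_input: str
    standardized_smiles: str | None = None
    inchi: str | None = None
    inchikey: str | None = None
    steps_applied: list[str] = field(default_factory=list)
    status: str = "ok"  # "ok" | "exception"
    flags: list[str] = field(default_factory=list)
    failing_step: str | None = None
    reason: str | None = None


@dataclass
class ExceptionQueueEntry:
    raw_input: str
    failing_step: str
    reason: str
    resolution: str | None = None  # manually supplied standardized SMILES


def _builtin_salt_path() -> Path:
    return Path(str(resources.files("lincskit") / "data" / "salts.smi"))


def load_salt_list(path: Path | str | None = None) -> frozenset[str]:
    """Canonical SMILES of the predefined salt/addend fragments."""
    path = Path(path) if path is not None else _builtin_salt_path()
    out = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles = line.split("\t")[0].strip()
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"salt list entry does not parse: {smiles!r}")
        out.add(Chem.MolToSmiles(mol))
    return frozenset(out)


_DEFAULT_SALTS: frozenset[str] | None = None


def _default_salts() -> frozenset[str]:
    global _DEFAULT_SALTS
    if _DEFAULT_SALTS is None:
        _DEFAULT_SALTS = load_salt_list()
    return _DEFAULT_SALTS


@dataclass
class _StepResult:
    mol: Chem.Mol
    flags: list[str] = field(default_factory=list)


def parse_structure(raw: str) -> Chem.Mol:
    """Parse SMILES or an SDF/MOL block; raises ValueError on failure."""
    raw = raw.strip()
    if not raw:
        raise ValueError("empty structure input")
    if "\n" in raw or raw.startswith(("M  END", "$$$$")):
        mol = Chem.MolFromMolBlock(raw)
    else:
        mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise ValueError(f"unparseable structure: {raw[:80]!r}")
    return mol


def strip_salts(mol: Chem.Mol,
                salt_smiles: frozenset[str] | None = None) -> _StepResult:
    """Remove fragments on the predefined salt/addend list.

    Single-fragment inputs pass through unchanged. If *every* fragment of a
    multi-fragment input is on the list there is no organic parent to keep;
    the largest fragment is retained and the record flagged for manual
    review.
    """
    salts = salt_smiles if salt_smiles is not None else _default_salts()
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) <= 1:
        return _StepResult(mol=mol)
    kept = [f for f in frags if Chem.MolToSmiles(f) not in salts]
    if not kept:
        largest = max(frags, key=lambda f: f.GetNumHeavyAtoms())
        return _StepResult(mol=largest, flags=["no-organic-parent"])
    out = kept[0]
    for f in kept[1:]:
        out = Chem.CombineMols(out, f)
    return _StepResult(mol=out)


def neutralize_charges(mol: Chem.Mol) -> _StepResult:
    """Protonate deprotonated acids, deprotonate protonated bases.

    Atom-by-atom: a negatively charged atom that can accept a proton gains
    one; a positively charged atom carrying hydrogens loses one. Permanent
    charges (quaternary nitrogen, charge-separated groups like nitro) are
    untouched; if the result still carries net charge the record is flagged
    ``residual-charge`` rather than failed.
    """
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge == 0:
            continue
        # skip charge-separated partners (e.g. N+ of nitro next to O-)
        if any(n.GetFormalCharge() * charge < 0
               for n in atom.GetNeighbors()):
            continue
        if charge < 0:
            atom.SetFormalCharge(charge + 1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        elif charge > 0 and atom.GetTotalNumHs() > 0:
            atom.SetFormalCharge(charge - 1)
            atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
        # positive with no H (quaternary N): permanent, leave it
    Chem.SanitizeMol(mol)
    flags = []
    if Chem.GetFormalCharge(mol) != 0:
        flags.append("residual-charge")
    return _StepResult(mol=mol, flags=flags)


_TAUTOMER_ENUMERATOR: rdMolStandardize.TautomerEnumerator | None = None


def canonical_tautomer(mol: Chem.Mol) -> Chem.Mol:
    """Deterministic canonical tautomer (formula-preserving, idempotent)."""
    global _TAUTOMER_ENUMERATOR
    if _TAUTOMER_ENUMERATOR is None:
        params = rdMolStandardize.CleanupParameters()
        # stereochemistry is carried through standardization verbatim
        params.tautomerRemoveSp3Stereo = False
        params.tautomerRemoveBondStereo = False
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator(params)
    out = _TAUTOMER_ENUMERATOR.Canonicalize(mol)
    if out is None:
        raise ValueError("tautomer canonicalization failed")
    return out


def standardize(raw_input: str,
                salt_smiles: frozenset[str] | None = None) -> StructureRecord:
    """Run the full rule sequence on one submitted structure.

    Returns a record with ``status="ok"`` and the canonical SMILES, InChI
    and InChIKey, or ``status="exception"`` naming the failing checkpoint.
    """
    record = StructureRecord(raw_input=raw_input)

    def fail(step: str, exc: Exception) -> StructureRecord:
        record.status = "exception"
        record.failing_step = step
        record.reason = str(exc)
        return record

    try:
        mol = parse_structure(raw_input)
    except Exception as exc:
        return fail("parse", exc)
    record.steps_applied.append("parse")

    try:
        res = strip_salts(mol, salt_smiles)
        mol, salt_flags = res.mol, res.flags
    except Exception as exc:
        return fail("strip_salts", exc)
    record.steps_applied.append("strip_salts")
    record.flags.extend(salt_flags)

    try:
        res = neutralize_charges(mol)
        mol = res.mol
        record.flags.extend(res.flags)
    except Exception as exc:
        return fail("neutralize", exc)
    record.steps_applied.append("neutralize")

    try:
        mol = canonical_tautomer(mol)
    except Exception as exc:
        return fail("tautomer", exc)
    record.steps_applied.append("tautomer")

    try:
        record.standardized_smiles = Chem.MolToSmiles(mol)
        record.inchi = Chem.MolToInchi(mol)
        record.inchikey = Chem.MolToInchiKey(mol)
        if not record.inchikey or len(record.inchikey) != 27:
            raise ValueError(f"malformed InChIKey {record.inchikey!r}")
    except Exception as exc:
        return fail("canonicalize", exc)
    record.steps_applied.append("canonicalize")

    if "no-organic-parent" in record.flags:
        # salts-only input: standardized form exists but needs human review
        record.status = "exception"
        record.failing_step = "strip_salts"
        record.reason = "all fragments on the salt/addend list"
    return record


def structure_key(record: StructureRecord,
                  connectivity_only: bool = False) -> str:
    """Canonical key for registration: the standardized InChIKey.

    With ``connectivity_only`` the first (skeleton) block of the key is
    used, collapsing stereoisomers onto one record; the default keeps the
    full key so stereoisomers register separately.
    """
    if record.status != "ok" or not record.inchikey:
        raise StandardizationRefused(
            f"record is not standardized (status={record.status!r}, "
            f"failing step {record.failing_step!r})")
    return record.inchikey.split("-")[0] if connectivity_only \
        else record.inchikey


def to_exception_entry(record: StructureRecord) -> ExceptionQueueEntry:
    if record.status != "exception":
        raise ValueError("record did not fail standardization")
    return ExceptionQueueEntry(raw_input=record.raw_input,
                               failing_step=record.failing_step or "?",
                               reason=record.reason or "")


def resolve_exception(entry: ExceptionQueueEntry,
                      resolved_smiles: str) -> StructureRecord:
    """Re-enter the pipeline with a manually curated structure."""
    entry.resolution = resolved_smiles
    return standardize(resolved_smiles)


def standardize_table(raw_inputs: list[tuple[str, str]],
                      salt_smiles: frozenset[str] | None = None,
                      ) -> tuple[list[tuple[str, StructureRecord]],
                                 list[ExceptionQueueEntry]]:
    """Standardize (id, structure) pairs; split ok records from the queue."""
    records, queue = [], []
    for input_id, raw in raw_inputs:
        rec = standardize(raw, salt_smiles)
        records.append((input_id, rec))
        if rec.status == "exception":
            queue.append(to_exception_entry(rec))
    return records, queue
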