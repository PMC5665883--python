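"""Ligand records, structure I/O, molecular descriptors and fingerprints.

This module is the chemistry substrate for the rest of the package: a
:class:`Ligand` is a single compound record (structure plus optional
activity annotation), :class:`DescriptorVector` carries the
physicochemical axes used for drug-likeness filtering and decoy matching,
and :class:`Fingerprint` wraps a Morgan (circular) bit fingerprint for
Tanimoto similarity.

All structures are canonicalized on ingest, so identity and similarity
comparisons never depend on how a SMILES happened to be written.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

logger = logging.getLogger(__name__)

# RDKit prints per-record parse errors to stderr; we count and log skips
# ourselves, so silence the C++ logger.
RDLogger.DisableLog("rdApp.error")

ROLES = ("active", "decoy", "candidate")
ACTIVITY_TYPES = ("Ki", "IC50", "none")

#: Column order of the ligand CSV dialect used throughout the package.
LIGAND_CSV_COLUMNS = (
    "id",
    "smiles",
    "role",
    "activity_type",
    "activity_value",
    "is_peptide",
)


class LigandError(ValueError):
    """Raised for unparseable structures or malformed ligand records."""


@dataclass(frozen=True)
class Ligand:
    """A compound record: accession, canonical structure and annotations.

    Parameters
    ----------
    id:
        Accession string (ZINC/ChEMBL/BindingDB id, or a synthetic id).
    smiles:
        Canonical SMILES. Use :func:`make_ligand` to canonicalize raw input.
    role:
        One of ``active`` (known binder), ``decoy`` (presumed non-binder)
        or ``candidate`` (screening hit of unknown activity).
    activity_value:
        Optional measured activity in micromolar; present iff
        ``activity_type`` is not ``"none"``.
    activity_type:
        ``"Ki"``, ``"IC50"`` or ``"none"``.
    heavy_atom_count:
        Number of non-hydrogen atoms of the parsed structure.
    is_peptide:
        Input annotation marking peptidic records; never inferred from
        the structure.
    """

    id: str
    smiles: str
    role: str = "candidate"
    activity_value: float | None = None
    activity_type: str = "none"
    heavy_atom_count: int = 0
    is_peptide: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LigandError(f"{self.id}: unknown role {self.role!r}")
        if self.activity_type not in ACTIVITY_TYPES:
            raise LigandError(
                f"{self.id}: unknown activity_type {self.activity_type!r}"
            )
        has_value = self.activity_value is not None
        if has_value != (self.activity_type != "none"):
            raise LigandError(
                f"{self.id}: activity_value must be present iff "
                f"activity_type != 'none'"
            )
        if has_value and self.activity_value <= 0:
            raise LigandError(f"{self.id}: activity_value must be positive")


@dataclass(frozen=True)
class DescriptorVector:
    """Physicochemical descriptors used for filtering and decoy matching."""

    mw: float
    clogp: float
    hba: int
    hbd: int
    rotatable_bonds: int
    net_charge: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if min(self.hba, self.hbd, self.rotatable_bonds) < 0:
            raise ValueError("descriptor counts must be non-negative")


@dataclass(frozen=True)
class Fingerprint:
    """Morgan circular fingerprint as a set of on-bit indices."""

    bits: frozenset[int]
    nbits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit index out of range")

    @property
    def popcount(self) -> int:
        return len(self.bits)


def _parse_mol(smiles: str, ligand_id: str = "?") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LigandError(f"{ligand_id}: unparseable structure {smiles!r}")
    return mol


def canonical_smiles(smiles: str, ligand_id: str = "?") -> str:
    """Canonical SMILES of a structure; idempotent by construction."""
    return Chem.MolToSmiles(_parse_mol(smiles, ligand_id))


def make_ligand(
    ligand_id: str,
    smiles: str,
    role: str = "candidate",
    activity_value: float | None = None,
    activity_type: str = "none",
    is_peptide: bool = False,
) -> Ligand:
    """Build a :class:`Ligand` from raw input, canonicalizing the structure
    and populating the heavy-atom count."""
    mol = _parse_mol(smiles, ligand_id)
    return Ligand(
        id=ligand_id,
        smiles=Chem.MolToSmiles(mol),
        role=role,
        activity_value=activity_value,
        activity_type=activity_type,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        is_peptide=is_peptide,
    )


def _parse_activity(raw_type: str, raw_value: str, ligand_id: str):
    """Parse optional activity columns; malformed values degrade to 'none'."""
    raw_type = (raw_type or "").strip()
    raw_value = (raw_value or "").strip()
    if not raw_type or raw_type.lower() == "none":
        return None, "none"
    if raw_type not in ("Ki", "IC50"):
        logger.warning("%s: unknown activity type %r, ignoring", ligand_id, raw_type)
        return None, "none"
    try:
        value = float(raw_value)
        if not math.isfinite(value) or value <= 0:
            raise ValueError
    except ValueError:
        logger.warning(
            "%s: malformed activity value %r, ignoring", ligand_id, raw_value
        )
        return None, "none"
    return value, raw_type


def read_ligands(path: str | Path, format: str | None = None) -> list[Ligand]:
    """Read ligand records from a ``.smi``, ``.sdf`` or ligand-CSV file.

    Unparseable records are skipped and counted (logged as a warning);
    zero valid records is an error. The CSV dialect is comma-separated
    with a required header ``id,smiles,...``; ``role``, activity columns
    and ``is_peptide`` are optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("smi", "sdf", "csv"):
        raise ValueError(f"unknown ligand format {format!r}")

    ligands: list[Ligand] = []
    n_skipped = 0

    if format == "smi":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                lid = parts[1].strip() if len(parts) > 1 else f"MOL{lineno:05d}"
                try:
                    ligands.append(make_ligand(lid, smiles))
                except LigandError:
                    n_skipped += 1
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                continue
            lid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"MOL{i + 1:05d}"
            if not lid:
                lid = f"MOL{i + 1:05d}"
            value, atype = None, "none"
            if mol.HasProp("activity_type"):
                value, atype = _parse_activity(
                    mol.GetProp("activity_type"),
                    mol.GetProp("activity_value") if mol.HasProp("activity_value") else "",
                    lid,
                )
            ligands.append(
                Ligand(
                    id=lid,
                    smiles=Chem.MolToSmiles(mol),
                    activity_value=value,
                    activity_type=atype,
                    heavy_atom_count=mol.GetNumHeavyAtoms(),
                )
            )
    else:  # csv
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise LigandError(f"{path}: ligand CSV requires a header with 'smiles'")
            for row in reader:
                lid = (row.get("id") or "").strip()
                try:
                    value, atype = _parse_activity(
                        row.get("activity_type", ""), row.get("activity_value", ""), lid
                    )
                    ligands.append(
                        make_ligand(
                            lid or f"MOL{reader.line_num:05d}",
                            (row.get("smiles") or "").strip(),
                            role=(row.get("role") or "candidate").strip() or "candidate",
                            activity_value=value,
                            activity_type=atype,
                            is_peptide=_parse_bool(row.get("is_peptide", "")),
                        )
                    )
                except LigandError:
                    n_skipped += 1

    if n_skipped:
        logger.warning("%s: skipped %d unparseable record(s)", path, n_skipped)
    if not ligands:
        raise LigandError(f"{path}: no valid ligand records")
    return ligands


def _parse_bool(raw: str | bool | None) -> bool:
    if isinstance(raw, bool):
        return raw
    return str(raw or "").strip().lower() in ("1", "true", "yes")


def write_ligands(ligands: Iterable[Ligand], path: str | Path) -> None:
    """Write ligands in the shared CSV dialect (round-trips with
    :func:`read_ligands`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LIGAND_CSV_COLUMNS)
        for lig in ligands:
            writer.writerow(
                [
                    lig.id,
                    lig.smiles,
                    lig.role,
                    lig.activity_type,
                    "" if lig.activity_value is None else repr(lig.activity_value),
                    str(lig.is_peptide).lower(),
                ]
            )


def compute_descriptors(ligand: Ligand) -> DescriptorVector:
    """Physicochemical descriptor vector of a ligand.

    H-bond acceptor/donor counts use the rule-of-five conventions
    (N+O and NH+OH counts respectively).
    """
    mol = _parse_mol(ligand.smiles, ligand.id)
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hba=rdMolDescriptors.CalcNumLipinskiHBA(mol),
        hbd=rdMolDescriptors.CalcNumLipinskiHBD(mol),
        rotatable_bonds=rdMolDescriptors.CalcNumRotatableBonds(mol),
        net_charge=Chem.GetFormalCharge(mol),
    )


def hetero_atom_count(ligand: Ligand) -> int:
    """Number of non-carbon, non-hydrogen atoms (an alternative atom-count
    basis for ligand efficiency)."""
    mol = _parse_mol(ligand.smiles, ligand.id)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))


def fingerprint(ligand: Ligand, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Morgan circular fingerprint of a ligand.

    Deterministic for a given canonical structure at fixed
    ``(radius, nbits)``; record both parameters alongside any reported
    Tanimoto value.
    """
    mol = _parse_mol(ligand.smiles, ligand.id)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| in [0, 1].

    0 means no bit overlap, 1 perfect overlap. The degenerate empty/empty
    case is defined as 0 (no overlap semantics).
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} != {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


#: Rule-of-five bounds: (descriptor field, max value, rule name).
LIPINSKI_RULES = (
    ("mw", 500.0, "mw>500"),
    ("clogp", 5.0, "clogp>5"),
    ("hbd", 5, "hbd>5"),
    ("hba", 10, "hba>10"),
)


def lipinski_pass(d: DescriptorVector) -> tuple[bool, list[str]]:
    """Rule-of-five drug-likeness check.

    Returns ``(passed, violations)`` where ``passed`` is True iff no rule
    is violated (mw ≤ 500, clogP ≤ 5, HBD ≤ 5, HBA ≤ 10).
    """
    violations = [
        name for attr, bound, name in LIPINSKI_RULES if getattr(d, attr) > bound
    ]
    return (not violations, violations)
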