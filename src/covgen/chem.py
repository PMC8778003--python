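"""Core molecule/fragment representation and the attachment-point grammar.

Fragments produced by the hierarchical Key/Value cutting scheme carry
explicit attachment tokens in their SMILES:

* ``[At]``  — the Value 1 attachment site on Key 1 / Key 2 cores (an
  astatine placeholder atom, chosen because it never occurs in drug-like
  molecules and survives SMILES canonicalization unchanged);
* ``[*:1]`` — the Value 2 attachment site on Key 2 cores (an atom-mapped
  dummy atom);
* ``*``     — the single attachment point of Value 1 / Value 2 substituents.

Fragment identity is constitution-based: stereochemistry is stripped when a
fragment is canonicalized, and reassembly equality is checked on achiral
canonical SMILES.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem, RDLogger
from rdkit.Chem.rdMolDescriptors import CalcMolFormula  # noqa: F401  (re-export for tests)

from .errors import AttachmentGrammarError, InvalidStructureError

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

#: atomic number of the astatine placeholder used for the Value 1 site
AT_PLACEHOLDER = 85
#: atom-map number marking the Value 2 site on Key 2 fragments
VALUE2_MAP = 1


class Role(str, enum.Enum):
    """Role of a fragment in the two-round cutting hierarchy."""

    KEY1 = "KEY1"
    KEY2 = "KEY2"
    VALUE1 = "VALUE1"
    VALUE2 = "VALUE2"


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`InvalidStructureError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(smiles)
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of *smiles*.

    Attachment tokens ([At], [*:1], bare ``*``) survive the round trip.
    Canonicalization is idempotent: ``canonicalize(canonicalize(s)) ==
    canonicalize(s)``.
    """
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def canonicalize_fragment(smiles: str) -> str:
    """Canonical, stereo-stripped SMILES used as fragment identity key."""
    mol = mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def constitution_key(smiles: str) -> str:
    """Achiral canonical SMILES, the equality key for reassembly checks."""
    return canonicalize_fragment(smiles)


def heavy_atom_count(mol: Chem.Mol, include_placeholders: bool = False) -> int:
    """Number of real heavy atoms; placeholders ([At], dummies) optionally included."""
    n = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z <= 1:
            continue
        if z == AT_PLACEHOLDER and not include_placeholders:
            continue
        n += 1
    return n


def attachment_atoms(mol: Chem.Mol) -> list[tuple[int, str]]:
    """Indices and labels of attachment atoms, in atom-index order.

    Labels are ``"[At]"``, ``"[*:1]"`` and ``"*"``.
    """
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == AT_PLACEHOLDER:
            out.append((atom.GetIdx(), "[At]"))
        elif atom.GetAtomicNum() == 0:
            if atom.GetAtomMapNum() == VALUE2_MAP:
                out.append((atom.GetIdx(), "[*:1]"))
            else:
                out.append((atom.GetIdx(), "*"))
    return out


#: attachment labels each role must carry, as a sorted tuple
_ROLE_GRAMMAR = {
    Role.KEY1: ("[At]",),
    Role.KEY2: ("[*:1]", "[At]"),
    Role.VALUE1: ("*",),
    Role.VALUE2: ("*",),
}


@dataclass(frozen=True)
class Molecule:
    """A complete (attachment-token-free) molecule."""

    smiles: str
    id: str
    heavy_atoms: int

    @classmethod
    def from_smiles(cls, smiles: str, id: str | None = None) -> "Molecule":
        mol = mol_from_smiles(smiles)
        if len(Chem.GetMolFrags(mol)) != 1:
            raise InvalidStructureError(smiles, "not a single connected molecule")
        if attachment_atoms(mol):
            raise InvalidStructureError(smiles, "molecule carries attachment tokens")
        canon = Chem.MolToSmiles(mol)
        return cls(smiles=canon, id=id if id is not None else canon,
                   heavy_atoms=heavy_atom_count(mol))

    def to_mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclass(frozen=True)
class Fragment:
    """A Key/Value fragment with role-specific attachment points."""

    smiles: str
    role: Role
    attachment_points: tuple[str, ...] = field(default=())

    @classmethod
    def from_smiles(cls, smiles: str, role: Role) -> "Fragment":
        """Canonicalize and validate the attachment grammar of *role*."""
        role = Role(role)
        mol = mol_from_smiles(smiles)
        labels = sorted(lbl for _, lbl in attachment_atoms(mol))
        expected = sorted(_ROLE_GRAMMAR[role])
        if labels != expected:
            raise AttachmentGrammarError(
                f"{role.value} fragment {smiles!r} has attachment points "
                f"{labels}, expected {expected}"
            )
        if heavy_atom_count(mol) == 0:
            raise AttachmentGrammarError(
                f"fragment {smiles!r} has no heavy atoms besides attachment tokens"
            )
        for idx, lbl in attachment_atoms(mol):
            if mol.GetAtomWithIdx(idx).GetDegree() != 1:
                raise AttachmentGrammarError(
                    f"attachment point {lbl} in {smiles!r} must have exactly one bond"
                )
        return cls(smiles=canonicalize_fragment(smiles), role=role,
                   attachment_points=tuple(_ROLE_GRAMMAR[role]))

    def to_mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)

    def heavy_atoms(self, include_placeholders: bool = False) -> int:
        return heavy_atom_count(self.to_mol(), include_placeholders)


#: default covalent warhead: N-acryloyl piperidine (Michael acceptor) with the
#: ring attached at any carbon; SMARTS "C" atoms allow ring substitution.
DEFAULT_WARHEAD_SMARTS = "C=CC(=O)N1CCCCC1"


@dataclass(frozen=True)
class WarheadPattern:
    """A reactive-group substructure pattern (SMARTS)."""

    smarts: str = DEFAULT_WARHEAD_SMARTS
    name: str = "acryloyl-piperidine"

    def query(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise InvalidStructureError(self.smarts, "SMARTS does not compile")
        return patt


def matches_warhead(entity: "Molecule | Fragment | str", pattern: WarheadPattern) -> bool:
    """True iff the molecule/fragment contains the warhead substructure."""
    smiles = entity if isinstance(entity, str) else entity.smiles
    return mol_from_smiles(smiles).HasSubstructMatch(pattern.query())


def read_molecules(path: str | Path) -> tuple[list[Molecule], int]:
    """Read a SMILES file (one record per line, optional tab/space ID) or SDF.

    Invalid records are skipped with a logged warning; returns the parsed
    molecules and the rejection count. IDs are auto-assigned (``M0001``...)
    when absent.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    mols: list[Molecule] = []
    rejected = 0

    def _add(smiles: str, mol_id: str | None, record: str):
        nonlocal rejected
        try:
            mols.append(Molecule.from_smiles(smiles, mol_id))
        except InvalidStructureError as exc:
            rejected += 1
            log.warning("skipping record %r: %s", record, exc)

    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                rejected += 1
                log.warning("skipping unparsable SDF record %d", i)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
            _add(Chem.MolToSmiles(mol), name or f"M{len(mols) + 1:04d}", f"sdf:{i}")
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"M{len(mols) + 1:04d}"
                _add(smiles, mol_id, line)
    if not mols and rejected == 0:
        raise OSError(f"empty input file: {path}")
    return mols, rejected


def write_smiles(path: str | Path, mols: list[Molecule]) -> None:
    """Write molecules as ``smiles<TAB>id`` lines."""
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.smiles}\t{m.id}\n")
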