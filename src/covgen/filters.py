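"""Selection stages for generated fragments.

Three stages mirror the design funnel: a rotatable-bond filter applied to
generated Key 2 cores (rigid, hinge-binding scaffolds only), a warhead
substructure filter applied to Value 2 fragments (the reactive group is
invariant), and a ring-system substructure census that flags Key 2
scaffolds absent from every reference set as novel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from rdkit import Chem

from .chem import (
    AT_PLACEHOLDER,
    Fragment,
    Molecule,
    Role,
    WarheadPattern,
    matches_warhead,
    mol_from_smiles,
)
from .errors import CovgenError, RoleError


@dataclass
class FilterReport:
    """Outcome of one filter stage; counts always reconcile."""

    input_count: int
    passed: list[Fragment]
    rejected_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        assert self.input_count == len(self.passed) + sum(self.rejected_counts.values())


def _is_attachment(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() == 0 or atom.GetAtomicNum() == AT_PLACEHOLDER


def _is_amide_bond(bond: Chem.Bond) -> bool:
    """C-N single bond where the carbon bears a double-bonded O (amide)."""
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c, n in ((a, b), (b, a)):
        if c.GetAtomicNum() == 6 and n.GetAtomicNum() == 7:
            for nb in c.GetBonds():
                other = nb.GetOtherAtom(c)
                if nb.GetBondType() == Chem.BondType.DOUBLE and other.GetAtomicNum() == 8:
                    return True
    return False


def count_rotatable_bonds(fragment: Fragment | Molecule | str,
                          exclude_amides: bool = True) -> int:
    """Rotatable bonds: single, non-ring bonds between two non-terminal
    heavy atoms, excluding amide C-N bonds (configurable) and any bond to
    an attachment token (formal, not conformational)."""
    smiles = fragment if isinstance(fragment, str) else fragment.smiles
    mol = mol_from_smiles(smiles)
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if _is_attachment(a) or _is_attachment(b):
            continue
        # terminal = a single heavy/token neighbour; tokens do not anchor rotation
        deg_a = sum(1 for x in a.GetNeighbors() if not _is_attachment(x))
        deg_b = sum(1 for x in b.GetNeighbors() if not _is_attachment(x))
        if deg_a < 2 or deg_b < 2:
            continue
        if exclude_amides and _is_amide_bond(bond):
            continue
        n += 1
    return n


def rotatable_bond_filter(fragments: Sequence[Fragment],
                          exclude_amides: bool = True) -> FilterReport:
    """Keep only fragments with zero rotatable bonds."""
    passed, rejected = [], 0
    for frag in fragments:
        if count_rotatable_bonds(frag, exclude_amides) == 0:
            passed.append(frag)
        else:
            rejected += 1
    counts = {"rotatable_bonds": rejected} if rejected else {}
    return FilterReport(input_count=len(fragments), passed=passed, rejected_counts=counts)


def warhead_filter(fragments: Sequence[Fragment], pattern: WarheadPattern) -> FilterReport:
    """Keep only VALUE2 fragments containing the warhead substructure."""
    passed, rejected = [], 0
    for frag in fragments:
        if frag.role is not Role.VALUE2:
            raise RoleError(f"warhead filter expects VALUE2 fragments, got {frag.role.value}")
        if matches_warhead(frag, pattern):
            passed.append(frag)
        else:
            rejected += 1
    counts = {"no_warhead": rejected} if rejected else {}
    return FilterReport(input_count=len(fragments), passed=passed, rejected_counts=counts)


def ring_system_query(fragment: Fragment | str) -> Chem.Mol:
    """The fragment's ring system as a substructure query.

    Attachment tokens are deleted, ring atoms are kept together with
    ring-attached heteroatom substituents (e.g. amino N, carbonyl O), and
    all cut positions are left open so any substitution matches.
    """
    smiles = fragment if isinstance(fragment, str) else fragment.smiles
    mol = mol_from_smiles(smiles)
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    if not ring_atoms:
        raise CovgenError(f"fragment {smiles!r} is acyclic; census needs a ring system")
    keep = set(ring_atoms)
    for idx in ring_atoms:
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetAtomicNum() not in (0, 1, 6, AT_PLACEHOLDER) and not nb.IsInRing():
                keep.add(nb.GetIdx())
    rw = Chem.RWMol(mol)
    drop = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in keep]
    for idx in drop:
        for nb in rw.GetAtomWithIdx(idx).GetNeighbors():
            # aromatic N losing its substituent needs the pyrrole-type H back;
            # H counts are no constraint in substructure matching, so the
            # query still matches any substitution at that position
            if nb.GetIsAromatic() and nb.GetAtomicNum() == 7:
                nb.SetNumExplicitHs(nb.GetTotalNumHs() + 1)
    for idx in sorted(drop, reverse=True):
        rw.RemoveAtom(idx)
    query = rw.GetMol()
    Chem.SanitizeMol(query)
    return query


def substructure_census(fragment: Fragment,
                        reference_sets: Mapping[str, Sequence[Molecule]]) -> dict[str, int]:
    """Count, per named reference set, the molecules containing the
    fragment's ring system as a substructure. Zero across all sets flags
    the fragment as novel."""
    query = ring_system_query(fragment)
    counts = {}
    for name, mols in reference_sets.items():
        counts[name] = sum(
            1 for m in mols if mol_from_smiles(m.smiles).HasSubstructMatch(query)
        )
    return counts


def is_novel(fragment: Fragment,
             reference_sets: Mapping[str, Sequence[Molecule]]) -> bool:
    """True iff the fragment's ring system occurs in no reference set."""
    return all(v == 0 for v in substructure_census(fragment, reference_sets).values())
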