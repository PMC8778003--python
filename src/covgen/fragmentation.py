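"""Hierarchical Key/Value fragmentation and SAR-matrix construction.

Compounds are cut twice at single acyclic bonds. Round one yields a Key 1
core (tagged ``[At]`` at the cut) and a Value 1 substituent (tagged ``*``);
round two cuts the Key 1 again into a Key 2 core (new cut tagged ``[*:1]``,
the round-one ``[At]`` retained) and a Value 2 fragment (tagged ``*``).
Every compound sharing a Key 2 belongs to one analogue-series matrix whose
rows are Value 2 variants and whose columns are Value 1 variants; occupied
cells are dataset compounds, empty cells are unexplored combinations.

Cut eligibility: single, non-ring bonds between heavy atoms, never touching
an attachment token and never inside a matched warhead (the reactive group
is invariant by design). The smaller side of a cut is the value and must
satisfy both size limits; a side already carrying attachment tokens is
always the key, which resolves the otherwise ambiguous equal-size case in
round two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from rdkit import Chem

from .chem import (
    AT_PLACEHOLDER,
    VALUE2_MAP,
    Fragment,
    Molecule,
    Role,
    WarheadPattern,
    attachment_atoms,
    constitution_key,
    mol_from_smiles,
)

_NEW_CUT_ISOTOPE = 99  # transient isotope tag for the freshly created dummy pair


@dataclass(frozen=True)
class FragmentationConfig:
    """Tunables of the cutting scheme.

    ``max_value_atoms``/``max_value_fraction`` bound the substituent size
    (heavy atoms, and fraction of the parent's heavy atoms).
    """

    max_value_atoms: int = 13
    max_value_fraction: float = 0.5
    warhead: WarheadPattern | None = None
    require_key2_ring: bool = True
    min_series_size: int = 2


@dataclass(frozen=True)
class Fragmentation:
    """One hierarchical decomposition of a parent molecule."""

    parent: Molecule
    key1: Fragment
    value1: Fragment
    key2: Fragment | None = None
    value2: Fragment | None = None

    def verify_reassembly(self) -> bool:
        """Reassembling the fragments reproduces the parent constitution."""
        from .assembly import assemble_compound, assemble_key1

        key1 = self.key1
        if self.key2 is not None:
            key1 = assemble_key1(self.key2, self.value2)
        mol = assemble_compound(key1, self.value1)
        return constitution_key(mol.smiles) == constitution_key(self.parent.smiles)


def _heavy_with_placeholders(mol: Chem.Mol, atom_ids) -> int:
    """Heavy atoms of a fragment side; [At] placeholders count, dummies do not."""
    n = 0
    for idx in atom_ids:
        z = mol.GetAtomWithIdx(idx).GetAtomicNum()
        if z > 1:  # includes AT_PLACEHOLDER, excludes the bare dummy (z=0)
            n += 1
    return n


def eligible_cut_bonds(mol: Chem.Mol, warhead: WarheadPattern | None = None) -> list[int]:
    """Bond indices that may be cut: single, acyclic, between heavy atoms,
    not touching attachment tokens, not inside a matched warhead."""
    protected: set[tuple[int, int]] = set()
    if warhead is not None:
        query = warhead.query()
        for match in mol.GetSubstructMatches(query):
            atoms = set(match)
            for bond in mol.GetBonds():
                if bond.GetBeginAtomIdx() in atoms and bond.GetEndAtomIdx() in atoms:
                    protected.add((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if a.GetAtomicNum() == AT_PLACEHOLDER or b.GetAtomicNum() == AT_PLACEHOLDER:
            continue
        if (a.GetIdx(), b.GetIdx()) in protected:
            continue
        out.append(bond.GetIdx())
    return out


def _split(mol: Chem.Mol, bond_idx: int) -> list[Chem.Mol] | None:
    """Cut one bond, tagging the two new dummies with a transient isotope.

    Returns the two sides, or None if the bond does not disconnect the graph.
    """
    cut = Chem.FragmentOnBonds(
        mol, [bond_idx], addDummies=True,
        dummyLabels=[(_NEW_CUT_ISOTOPE, _NEW_CUT_ISOTOPE)],
    )
    sides = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
    if len(sides) != 2:
        return None
    return list(sides)


def _finish_side(side: Chem.Mol, as_key: bool, key_role: Role) -> str:
    """Convert the transient cut dummy into its final attachment token."""
    rw = Chem.RWMol(side)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope() == _NEW_CUT_ISOTOPE:
            atom.SetIsotope(0)
            if as_key:
                if key_role is Role.KEY1:
                    atom.SetAtomicNum(AT_PLACEHOLDER)
                    atom.SetAtomMapNum(0)
                else:
                    atom.SetAtomMapNum(VALUE2_MAP)
            else:
                atom.SetAtomMapNum(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def enumerate_single_cuts(
    entity: Molecule | Fragment,
    config: FragmentationConfig = FragmentationConfig(),
    key_role: Role = Role.KEY1,
    value_role: Role = Role.VALUE1,
) -> list[tuple[Fragment, Fragment]]:
    """All qualifying single cuts of *entity*, as (key, value) fragment pairs.

    Deduplicated by canonical fragment SMILES (symmetric cuts collapse) and
    emitted in lexicographic order for determinism.
    """
    mol = mol_from_smiles(entity.smiles)
    parent_heavy = _heavy_with_placeholders(mol, range(mol.GetNumAtoms()))
    results: dict[tuple[str, str], tuple[Fragment, Fragment]] = {}
    for bond_idx in eligible_cut_bonds(mol, config.warhead):
        sides = _split(mol, bond_idx)
        if sides is None:
            continue
        counts = [_heavy_with_placeholders(s, range(s.GetNumAtoms())) for s in sides]
        has_tokens = [
            any(a.GetAtomicNum() == AT_PLACEHOLDER
                or (a.GetAtomicNum() == 0 and a.GetIsotope() != _NEW_CUT_ISOTOPE)
                for a in s.GetAtoms())
            for s in sides
        ]
        if all(has_tokens):
            continue  # value side may carry only the new cut point
        if any(has_tokens):
            key_i = has_tokens.index(True)
        elif counts[0] != counts[1]:
            key_i = counts.index(max(counts))
        else:
            # equal sizes: the value is the side whose value-form canonical
            # SMILES sorts first (deterministic, representation-independent)
            value_forms = [_finish_side(s, False, key_role) for s in sides]
            key_i = value_forms.index(max(value_forms))
        val_i = 1 - key_i
        if counts[val_i] > config.max_value_atoms:
            continue
        if counts[val_i] > config.max_value_fraction * parent_heavy:
            continue
        if (key_role is Role.KEY2 and config.require_key2_ring
                and sides[key_i].GetRingInfo().NumRings() == 0):
            continue
        key = Fragment.from_smiles(_finish_side(sides[key_i], True, key_role), key_role)
        value = Fragment.from_smiles(_finish_side(sides[val_i], False, key_role), value_role)
        results[(key.smiles, value.smiles)] = (key, value)
    return [results[k] for k in sorted(results)]


def fragment_hierarchical(
    mol: Molecule, config: FragmentationConfig = FragmentationConfig()
) -> list[Fragmentation]:
    """Two-round fragmentation: every round-one cut crossed with every
    qualifying round-two cut of its Key 1."""
    out: list[Fragmentation] = []
    for key1, value1 in enumerate_single_cuts(mol, config, Role.KEY1, Role.VALUE1):
        for key2, value2 in enumerate_single_cuts(key1, config, Role.KEY2, Role.VALUE2):
            out.append(Fragmentation(parent=mol, key1=key1, value1=value1,
                                     key2=key2, value2=value2))
    out.sort(key=lambda f: (f.key2.smiles, f.value2.smiles, f.value1.smiles))
    return out


@dataclass
class SARMatrix:
    """One analogue-series matrix: a shared Key 2 core, Value 2 rows,
    Value 1 columns, and dataset compounds in the occupied cells."""

    key2: Fragment
    rows: tuple[Fragment, ...]
    columns: tuple[Fragment, ...]
    cells: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rows), len(self.columns)

    @property
    def n_occupied(self) -> int:
        return len(self.cells)

    @property
    def n_empty(self) -> int:
        return len(self.rows) * len(self.columns) - len(self.cells)

    def compound_ids(self) -> set[str]:
        return set(self.cells.values())


def build_sarms(
    dataset: list[Molecule], config: FragmentationConfig = FragmentationConfig()
) -> list[SARMatrix]:
    """Index every hierarchical fragmentation of the dataset into matrices.

    One matrix per Key 2 occurring in at least ``config.min_series_size``
    distinct compounds. Rows/columns are deduplicated by canonical fragment
    SMILES and sorted lexicographically.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    by_key2: dict[str, dict[tuple[str, str], str]] = {}
    frag_cache: dict[str, Fragment] = {}
    for mol in sorted(dataset, key=lambda m: (m.smiles, m.id)):
        for f in fragment_hierarchical(mol, config):
            frag_cache[f.key2.smiles] = f.key2
            frag_cache[f.value2.smiles] = f.value2
            frag_cache[f.value1.smiles] = f.value1
            cellmap = by_key2.setdefault(f.key2.smiles, {})
            cellmap.setdefault((f.value2.smiles, f.value1.smiles), mol.id)
    matrices = []
    for key2_smiles in sorted(by_key2):
        cellmap = by_key2[key2_smiles]
        compounds = set(cellmap.values())
        if len(compounds) < config.min_series_size:
            continue
        row_smis = sorted({v2 for v2, _ in cellmap})
        col_smis = sorted({v1 for _, v1 in cellmap})
        cells = {
            (row_smis.index(v2), col_smis.index(v1)): mol_id
            for (v2, v1), mol_id in cellmap.items()
        }
        # the same canonical SMILES (bare * substituent) can occur in both
        # value roles; pin the role by matrix position
        matrices.append(SARMatrix(
            key2=frag_cache[key2_smiles],
            rows=tuple(replace(frag_cache[s], role=Role.VALUE2) for s in row_smis),
            columns=tuple(replace(frag_cache[s], role=Role.VALUE1) for s in col_smis),
            cells=cells,
        ))
    return matrices
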