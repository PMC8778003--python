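"""Cutting scheme, hierarchical fragmentation, SAR-matrix construction.

``brute_force_cuts`` is an independent oracle: it enumerates bonds with
explicit ring-membership/eligibility tests, splits sides by its own BFS
over the adjacency list, and builds the tagged fragments by direct RWMol
editing (a different code path from the implementation's FragmentOnBonds).
"""

import pytest
from rdkit import Chem

from covgen.chem import (
    AT_PLACEHOLDER,
    Fragment,
    Molecule,
    Role,
    canonicalize_fragment,
)
from covgen.fragmentation import (
    FragmentationConfig,
    build_sarms,
    enumerate_single_cuts,
    fragment_hierarchical,
)
from covgen.assembly import assemble_compound, assemble_key1
from covgen.fixtures import IBRUTINIB_KEY2, IBRUTINIB_VALUE1, IBRUTINIB_VALUE2


def brute_force_cuts(smiles, config, key_role=Role.KEY1, value_role=Role.VALUE1):
    """Oracle enumeration of qualifying single cuts (see module docstring)."""
    mol = Chem.MolFromSmiles(smiles)
    ring_bonds = set()
    for ring in mol.GetRingInfo().BondRings():
        ring_bonds.update(ring)
    protected = set()
    if config.warhead is not None:
        for match in mol.GetSubstructMatches(config.warhead.query()):
            ms = set(match)
            for b in mol.GetBonds():
                if b.GetBeginAtomIdx() in ms and b.GetEndAtomIdx() in ms:
                    protected.add(b.GetIdx())

    def side_atoms(removed_bond, start):
        adj = {a.GetIdx(): [n.GetIdx() for n in a.GetNeighbors()] for a in mol.GetAtoms()}
        i, j = removed_bond
        seen, stack = set(), [start]
        while stack:
            a = stack.pop()
            if a in seen:
                continue
            seen.add(a)
            for n in adj[a]:
                if {a, n} == {i, j}:
                    continue
                stack.append(n)
        return seen

    def heavy(atoms):
        return sum(1 for a in atoms if mol.GetAtomWithIdx(a).GetAtomicNum() > 1)

    def tokens(atoms):
        return any(mol.GetAtomWithIdx(a).GetAtomicNum() in (0, AT_PLACEHOLDER)
                   for a in atoms)

    def side_smiles(atoms, cut_atom, token):
        rw = Chem.RWMol(mol)
        dummy = rw.AddAtom(Chem.Atom(token))
        rw.AddBond(cut_atom, dummy, Chem.BondType.SINGLE)
        if token == 0 and key_role is Role.KEY2 and cut_atom in key_side_flag:
            rw.GetAtomWithIdx(dummy).SetAtomMapNum(1)
        drop = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in atoms]
        for idx in sorted(drop, reverse=True):
            rw.RemoveAtom(idx)
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return canonicalize_fragment(Chem.MolToSmiles(out))

    results = set()
    parent_heavy = heavy(range(mol.GetNumAtoms()))
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if bond.GetIdx() in ring_bonds or bond.GetIdx() in protected:
            continue
        bi, bj = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        za = mol.GetAtomWithIdx(bi).GetAtomicNum()
        zb = mol.GetAtomWithIdx(bj).GetAtomicNum()
        if za <= 1 or zb <= 1 or AT_PLACEHOLDER in (za, zb) or 0 in (za, zb):
            continue
        side_i = side_atoms((bi, bj), bi)
        side_j = side_atoms((bi, bj), bj)
        tok_i, tok_j = tokens(side_i), tokens(side_j)
        if tok_i and tok_j:
            continue
        if tok_i or tok_j:
            key_side, val_side = (side_i, side_j) if tok_i else (side_j, side_i)
            key_cut, val_cut = (bi, bj) if tok_i else (bj, bi)
        else:
            hi, hj = heavy(side_i), heavy(side_j)
            if hi != hj:
                bigger_is_i = hi > hj
            else:
                # tie-break contract: the value is the side whose value-form
                # canonical SMILES sorts first
                key_side_flag = set()
                si = side_smiles(side_i, bi, 0)
                sj = side_smiles(side_j, bj, 0)
                bigger_is_i = si > sj
            key_side, val_side = ((side_i, side_j) if bigger_is_i else (side_j, side_i))
            key_cut, val_cut = ((bi, bj) if bigger_is_i else (bj, bi))
        hv = heavy(val_side)
        if hv > config.max_value_atoms or hv > config.max_value_fraction * parent_heavy:
            continue
        if key_role is Role.KEY2 and config.require_key2_ring:
            if not any(mol.GetAtomWithIdx(a).IsInRing() for a in key_side):
                continue
        key_side_flag = {key_cut}
        key_token = AT_PLACEHOLDER if key_role is Role.KEY1 else 0
        results.add((side_smiles(key_side, key_cut, key_token),
                     side_smiles(val_side, val_cut, 0)))
    return results


class TestEnumerateSingleCuts:
    def test_ethane_single_symmetric_cut(self):
        cuts = enumerate_single_cuts(Molecule.from_smiles("CC"))
        assert [(k.smiles, v.smiles) for k, v in cuts] == [("C[At]", "*C")]

    def test_benzene_has_no_acyclic_bonds(self):
        assert enumerate_single_cuts(Molecule.from_smiles("c1ccccc1")) == []

    def test_agrees_with_brute_force_on_ibrutinib(self, ibrutinib, frag_config):
        mol, *_ = ibrutinib
        got = {(k.smiles, v.smiles)
               for k, v in enumerate_single_cuts(mol, frag_config)}
        expected = brute_force_cuts(mol.smiles, frag_config)
        assert got == expected

    def test_agrees_with_brute_force_on_library_sample(self, small_library, frag_config):
        pretrain, _ = small_library
        for mol in pretrain[::7]:
            got = {(k.smiles, v.smiles)
                   for k, v in enumerate_single_cuts(mol, frag_config)}
            assert got == brute_force_cuts(mol.smiles, frag_config), mol.smiles

    def test_warhead_bonds_never_cut(self, frag_config, warhead):
        # N-acryloylpiperidine itself: every acyclic bond is inside the warhead
        mol = Molecule.from_smiles("C=CC(=O)N1CCCCC1")
        assert enumerate_single_cuts(mol, frag_config) == []


class TestHierarchical:
    def test_ibrutinib_reference_decomposition_present(self, ibrutinib, frag_config):
        mol, key2, value2, value1 = ibrutinib
        frs = fragment_hierarchical(mol, frag_config)
        hits = [f for f in frs if f.key2.smiles == IBRUTINIB_KEY2]
        assert len(hits) == 1
        assert hits[0].value2.smiles == canonicalize_fragment(IBRUTINIB_VALUE2)
        assert hits[0].value1.smiles == canonicalize_fragment(IBRUTINIB_VALUE1)

    def test_benzene_empty(self, frag_config):
        assert fragment_hierarchical(Molecule.from_smiles("c1ccccc1"), frag_config) == []

    def test_cartesian_expansion_counts(self, frag_config):
        # biphenyl with two methyls: each round-1 cut of a methyl leaves a
        # key with exactly one qualifying ring-preserving second cut set
        mol = Molecule.from_smiles("Cc1ccc(-c2ccc(C)cc2)cc1")
        frs = fragment_hierarchical(mol, frag_config)
        first = enumerate_single_cuts(mol, frag_config)
        expected = sum(
            len(enumerate_single_cuts(k, frag_config, Role.KEY2, Role.VALUE2))
            for k, _ in first
        )
        assert len(frs) == expected > 0

    def test_reassembly_closure_on_sample(self, small_library, frag_config):
        pretrain, _ = small_library
        for mol in pretrain[::5]:
            frs = fragment_hierarchical(mol, frag_config)
            assert frs, mol.smiles
            assert all(f.verify_reassembly() for f in frs), mol.smiles


@pytest.fixture(scope="module")
def series(frag_config):
    key2 = Fragment.from_smiles(IBRUTINIB_KEY2, Role.KEY2)
    v2s = [Fragment.from_smiles(s, Role.VALUE2)
           for s in ("*C1CCCN(C(=O)C=C)C1", "*C1CCN(C(=O)C=C)CC1")]
    v1s = [Fragment.from_smiles(s, Role.VALUE1)
           for s in ("*c1ccccc1", "*c1ccc(F)cc1")]
    mols = [
        Molecule.from_smiles(
            assemble_compound(assemble_key1(key2, v2), v1).smiles, f"c{i}")
        for i, (v2, v1) in enumerate(
            (v2, v1) for v2 in v2s for v1 in v1s)
    ]
    return key2, mols


class TestSARMatrix:
    def test_full_2x2_series(self, series, frag_config):
        key2, mols = series
        matrices = {m.key2.smiles: m for m in build_sarms(mols, frag_config)}
        m = matrices[key2.smiles]
        assert m.shape == (2, 2) and m.n_occupied == 4 and m.n_empty == 0

    def test_missing_compound_leaves_empty_cell(self, series, frag_config):
        key2, mols = series
        matrices = {m.key2.smiles: m for m in build_sarms(mols[:3], frag_config)}
        m = matrices[key2.smiles]
        assert m.n_occupied == 3 and m.n_empty == 1

    def test_singletons_make_no_matrix(self, frag_config):
        mols = [Molecule.from_smiles("CCOc1ccccc1", "a"),
                Molecule.from_smiles("CCCCNC1CCCCC1", "b")]
        assert build_sarms(mols, frag_config) == []

    def test_occupied_cells_match_fragmentation_index(self, small_library, frag_config):
        """Matrix completeness: occupied cells across all matrices equal the
        distinct (Key2, Value2, Value1) triples of compounds with series support."""
        pretrain, _ = small_library
        subset = pretrain[:40]
        matrices = build_sarms(subset, frag_config)
        triples = {}
        for mol in subset:
            for f in fragment_hierarchical(mol, frag_config):
                triples.setdefault(
                    (f.key2.smiles, f.value2.smiles, f.value1.smiles), set()
                ).add(mol.id)
        support = {}
        for (k2, v2, v1), ids in triples.items():
            support.setdefault(k2, set()).update(ids)
        expected = sum(
            1 for (k2, v2, v1) in triples
            if len(support[k2]) >= frag_config.min_series_size
        )
        assert sum(m.n_occupied for m in matrices) == expected
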