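"""Fragment re-assembly and candidate-matrix construction.

Assembly inverts the cutting scheme: a Key 2 and a Value 2 joined at the
``[*:1]``/``*`` pair give a Key 1 core; a Key 1 and a Value 1 joined at the
``[At]``/``*`` pair give a complete candidate molecule. A per-Key-2
candidate matrix crosses warhead-bearing Value 2 rows with top-ranked
Value 1 columns; each cell holds an assembled candidate with a cumulative
novelty score (mean of the three fragment scores, clipped to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem

from .chem import (
    AT_PLACEHOLDER,
    VALUE2_MAP,
    Fragment,
    Molecule,
    Role,
    mol_from_smiles,
)
from .errors import AssemblyError, AttachmentGrammarError

_ZIP_MAP = 77  # transient map number pairing the two attachment atoms for molzip


def _prepare(smiles: str, site: str) -> Chem.Mol:
    """Convert the attachment atom selected by *site* into a molzip dummy."""
    mol = Chem.RWMol(mol_from_smiles(smiles))
    hits = 0
    for atom in mol.GetAtoms():
        if site == "[At]" and atom.GetAtomicNum() == AT_PLACEHOLDER:
            atom.SetAtomicNum(0)
            atom.SetAtomMapNum(_ZIP_MAP)
            hits += 1
        elif site == "[*:1]" and atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == VALUE2_MAP:
            atom.SetAtomMapNum(_ZIP_MAP)
            hits += 1
        elif site == "*" and atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 0:
            atom.SetAtomMapNum(_ZIP_MAP)
            hits += 1
    if hits != 1:
        raise AttachmentGrammarError(
            f"fragment {smiles!r} has {hits} {site} attachment sites, expected 1"
        )
    return mol.GetMol()


def _zip(a: Chem.Mol, b: Chem.Mol) -> Chem.Mol:
    # generated fragments can be grammatically valid yet chemically
    # unjoinable (e.g. aromatic valence conflicts at the new bond)
    try:
        out = Chem.molzip(Chem.CombineMols(a, b))
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise AssemblyError(f"fragments cannot be joined: {exc}") from exc
    return out


def assemble_key1(key2: Fragment, value2: Fragment) -> Fragment:
    """Bond a Value 2 substituent onto a Key 2 core's ``[*:1]`` site."""
    if key2.role is not Role.KEY2 or value2.role is not Role.VALUE2:
        raise AttachmentGrammarError(
            f"assemble_key1 needs (KEY2, VALUE2), got ({key2.role.value}, {value2.role.value})"
        )
    joined = _zip(_prepare(key2.smiles, "[*:1]"), _prepare(value2.smiles, "*"))
    return Fragment.from_smiles(Chem.MolToSmiles(joined), Role.KEY1)


def assemble_compound(key1: Fragment, value1: Fragment) -> Molecule:
    """Bond a Value 1 substituent onto a Key 1 core's ``[At]`` site."""
    if key1.role is not Role.KEY1 or value1.role is not Role.VALUE1:
        raise AttachmentGrammarError(
            f"assemble_compound needs (KEY1, VALUE1), got ({key1.role.value}, {value1.role.value})"
        )
    joined = _zip(_prepare(key1.smiles, "[At]"), _prepare(value1.smiles, "*"))
    smiles = Chem.MolToSmiles(joined)
    for atom in joined.GetAtoms():
        if atom.GetAtomicNum() == 0 or atom.GetAtomicNum() == AT_PLACEHOLDER:
            raise AssemblyError(f"residual attachment token in assembled molecule {smiles!r}")
    return Molecule.from_smiles(smiles)


@dataclass
class Candidate:
    """An assembled ([Key 2 − Value 2] − Value 1) candidate compound."""

    key2: Fragment
    value2: Fragment
    value1: Fragment
    molecule: Molecule
    cumulative_score: float
    pharmacophore_fit: float | None = None


@dataclass
class CandidateMatrix:
    """Per-Key-2 design matrix: Value 2 rows x Value 1 columns of candidates."""

    key2: Fragment
    rows: tuple[Fragment, ...]
    columns: tuple[Fragment, ...]
    cells: dict[tuple[int, int], Candidate] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rows), len(self.columns)

    def candidates(self) -> list[Candidate]:
        return [self.cells[k] for k in sorted(self.cells)]


def cumulative_score(key2_score: float, value2_score: float, value1_score: float) -> float:
    """Mean of the three per-fragment novelty scores, clipped to [0, 1]."""
    s = (key2_score + value2_score + value1_score) / 3.0
    return min(1.0, max(0.0, s))


ScoredFragment = tuple[Fragment, float]


def build_candidate_matrix(
    key2: ScoredFragment,
    value2s: Sequence[ScoredFragment],
    value1s_per_key1: dict[str, Sequence[ScoredFragment]],
    top_k: int = 100,
    shared_columns: bool = True,
) -> CandidateMatrix:
    """Cross Value 2 rows with top-k Value 1 columns under one Key 2.

    ``value1s_per_key1`` maps each Key 1 canonical SMILES (one per Value 2
    row) to its sampled, scored Value 1 fragments. With ``shared_columns``
    the per-Key-1 top-k lists are merged, re-ranked by best (lowest) score
    and truncated to ``top_k``, giving one column set for all rows; without
    it, each row keeps its own top-k and the column set is their union.
    Duplicate candidates (same canonical molecule) keep the lowest score.
    """
    if not value2s:
        raise AssemblyError("no Value 2 rows: empty candidate matrix")
    key2_frag, key2_score = key2
    rows = sorted(value2s, key=lambda fs: fs[0].smiles)

    key1_for_row: dict[int, Fragment] = {}
    per_row_ranked: dict[int, list[ScoredFragment]] = {}
    for i, (v2, _) in enumerate(rows):
        try:
            key1 = assemble_key1(key2_frag, v2)
        except AssemblyError:
            per_row_ranked[i] = []
            continue
        key1_for_row[i] = key1
        sampled = value1s_per_key1.get(key1.smiles, ())
        ranked = sorted(sampled, key=lambda fs: (fs[1], fs[0].smiles))[:top_k]
        per_row_ranked[i] = ranked

    best_score: dict[str, float] = {}
    frag_by_smiles: dict[str, Fragment] = {}
    if shared_columns:
        for ranked in per_row_ranked.values():
            for frag, score in ranked:
                frag_by_smiles[frag.smiles] = frag
                if score < best_score.get(frag.smiles, float("inf")):
                    best_score[frag.smiles] = score
        ordered = sorted(best_score, key=lambda s: (best_score[s], s))[:top_k]
    else:
        for ranked in per_row_ranked.values():
            for frag, score in ranked:
                frag_by_smiles[frag.smiles] = frag
                if score < best_score.get(frag.smiles, float("inf")):
                    best_score[frag.smiles] = score
        ordered = sorted(best_score, key=lambda s: (best_score[s], s))

    columns = tuple(frag_by_smiles[s] for s in ordered)
    col_index = {s: j for j, s in enumerate(ordered)}

    matrix = CandidateMatrix(key2=key2_frag, rows=tuple(f for f, _ in rows), columns=columns)
    seen_molecules: dict[str, tuple[int, int]] = {}
    for i, (v2, v2_score) in enumerate(rows):
        if i not in key1_for_row:
            continue
        usable = ordered if shared_columns else [f.smiles for f, _ in per_row_ranked[i]]
        for smi in usable:
            j = col_index[smi]
            v1 = frag_by_smiles[smi]
            try:
                mol = assemble_compound(key1_for_row[i], v1)
            except AssemblyError:
                continue  # chemically unjoinable combination; cell stays empty
            score = cumulative_score(key2_score, v2_score, best_score[smi])
            if mol.smiles in seen_molecules:
                prev = matrix.cells[seen_molecules[mol.smiles]]
                if score < prev.cumulative_score:
                    del matrix.cells[seen_molecules[mol.smiles]]
                else:
                    continue
            matrix.cells[(i, j)] = Candidate(
                key2=key2_frag, value2=v2, value1=v1,
                molecule=mol, cumulative_score=score,
            )
            seen_molecules[mol.smiles] = (i, j)
    return matrix
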