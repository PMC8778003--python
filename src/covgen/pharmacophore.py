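"""Self-contained 3D pharmacophore models with exclusion volumes.

A model is a typed set of 3D interaction features (hydrogen-bond donor and
acceptor, aromatic-ring centroid, hydrophobic centroid, and a residue
bonding point marking the warhead's Michael-acceptor carbon) with
per-feature tolerance radii, optional flags, and forbidden exclusion-volume
spheres. Candidate molecules are embedded into an ensemble of force-field
relaxed conformers; each conformer's perceived features are assigned to
type-compatible model features, superposed by rigid-body least squares, and
scored

    score = (1 / n_features) * sum over matched features of exp(-d_i / 2 A)

where d_i is the residual feature-pair distance after superposition and a
feature is matched when that distance lies within the model feature's
radius. Any heavy atom landing inside an exclusion volume is a steric
clash and zeroes the conformer's score. The best score over all conformers
and assignments is reported (a 'best conformation match' surrogate).

The per-feature exponential form coincides with a match-fraction times
exp(-rmsd/2) score when matched distances are equal (e.g. a self fit), and
is monotone under both radius widening and exclusion-volume removal for
any fixed conformer/assignment, which keeps the filter's behaviour
predictable. It is a fully specified surrogate, not a re-implementation of
any proprietary scoring function.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import (
    AT_PLACEHOLDER,
    Fragment,
    Molecule,
    WarheadPattern,
    mol_from_smiles,
)
from .errors import ConformerError, CovgenError


class FeatureType(str, enum.Enum):
    HBD = "HBD"
    HBA = "HBA"
    AROMATIC = "AROMATIC"
    HYDROPHOBIC = "HYDROPHOBIC"
    RESIDUE_BONDING_POINT = "RESIDUE_BONDING_POINT"


@dataclass(frozen=True)
class Feature:
    type: FeatureType
    position: tuple[float, float, float]
    radius: float = 1.5
    optional: bool = False

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")


@dataclass(frozen=True)
class ExclusionVolume:
    position: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("exclusion radius must be positive")


@dataclass(frozen=True)
class PharmacophoreModel:
    features: tuple[Feature, ...]
    exclusion_volumes: tuple[ExclusionVolume, ...] = ()

    def __post_init__(self):
        if not any(not f.optional for f in self.features):
            raise ValueError("model needs at least one required feature")

    @property
    def required(self) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if not f.optional)

    def to_dict(self) -> dict:
        return {
            "features": [
                {"type": f.type.value, "xyz": list(f.position),
                 "radius": f.radius, "optional": f.optional}
                for f in self.features
            ],
            "exclusions": [
                {"xyz": list(e.position), "radius": e.radius}
                for e in self.exclusion_volumes
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict) -> "PharmacophoreModel":
        return cls(
            features=tuple(
                Feature(FeatureType(f["type"]), tuple(f["xyz"]),
                        f.get("radius", 1.5), f.get("optional", False))
                for f in data["features"]
            ),
            exclusion_volumes=tuple(
                ExclusionVolume(tuple(e["xyz"]), e["radius"])
                for e in data.get("exclusions", [])
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PharmacophoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PharmacophoreModel":
        """The model under a rigid motion x -> R x + t (features and exclusions)."""
        def mv(p):
            return tuple((rotation @ np.asarray(p) + translation).tolist())
        return PharmacophoreModel(
            features=tuple(Feature(f.type, mv(f.position), f.radius, f.optional)
                           for f in self.features),
            exclusion_volumes=tuple(ExclusionVolume(mv(e.position), e.radius)
                                    for e in self.exclusion_volumes),
        )


@dataclass
class ConformerSet:
    molecule: Chem.Mol  # with explicit hydrogens and embedded conformers
    conformers: list[np.ndarray]  # (n_atoms, 3) each
    seed: int


@dataclass
class FitResult:
    best_score: float
    matched_features: int
    rmsd: float
    conformer_index: int
    clash: bool
    fit: bool  # all required features matched and no clash


def cap_attachment_points(fragment: Fragment | str) -> Molecule:
    """Replace attachment tokens ([At], dummies) with hydrogen for 3D work."""
    smiles = fragment if isinstance(fragment, str) else fragment.smiles
    rw = Chem.RWMol(mol_from_smiles(smiles))
    tokens = [a.GetIdx() for a in rw.GetAtoms()
              if a.GetAtomicNum() in (0, AT_PLACEHOLDER)]
    for idx in tokens:
        for nb in rw.GetAtomWithIdx(idx).GetNeighbors():
            # an aromatic N losing its substituent needs the pyrrole-type H back
            if nb.GetIsAromatic() and nb.GetAtomicNum() == 7:
                nb.SetNumExplicitHs(nb.GetTotalNumHs() + 1)
    for idx in sorted(tokens, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Molecule.from_smiles(Chem.MolToSmiles(out))


def generate_conformers(mol: Molecule, n: int, seed: int,
                        max_heavy_atoms: int = 100) -> ConformerSet:
    """Embed up to *n* conformers (distance-geometry) and relax with MMFF
    (UFF fallback). Deterministic for a fixed seed."""
    if n <= 0:
        raise ValueError("conformer count must be positive")
    rdmol = mol_from_smiles(mol.smiles)
    if rdmol.GetNumHeavyAtoms() > max_heavy_atoms:
        raise ConformerError(f"molecule exceeds {max_heavy_atoms} heavy atoms")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    conf_ids = AllChem.EmbedMultipleConfs(rdmol, numConfs=n, params=params)
    if not conf_ids:
        raise ConformerError(f"embedding failed for {mol.smiles!r}")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(rdmol, maxIters=500)
    except Exception:
        AllChem.UFFOptimizeMoleculeConfs(rdmol, maxIters=500)
    coords = [np.array(rdmol.GetConformer(cid).GetPositions()) for cid in conf_ids]
    return ConformerSet(molecule=rdmol, conformers=coords, seed=seed)


def _hydrophobic_components(mol: Chem.Mol) -> list[list[int]]:
    """Maximal connected sets of >=3 aliphatic carbons with only C/H neighbours."""
    eligible = set()
    for a in mol.GetAtoms():
        if a.GetAtomicNum() != 6 or a.GetIsAromatic():
            continue
        if all(nb.GetAtomicNum() in (1, 6) for nb in a.GetNeighbors()):
            eligible.add(a.GetIdx())
    seen, comps = set(), []
    for start in sorted(eligible):
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetIdx() in eligible and nb.GetIdx() not in seen:
                    stack.append(nb.GetIdx())
        if len(comp) >= 3:
            comps.append(sorted(comp))
    return comps


def perceive_features(mol: Chem.Mol, coords: np.ndarray,
                      warhead: WarheadPattern | None = None) -> list[tuple[FeatureType, np.ndarray]]:
    """Rule-based feature perception on one conformer.

    HBD: N/O bearing a hydrogen. HBA: any O, or N with a free lone pair
    (uncharged, not a ring NH, fewer than four connections). AROMATIC: one
    feature per aromatic-ring centroid. HYDROPHOBIC: centroid of each
    connected run of three or more carbon-only aliphatic carbons.
    RESIDUE_BONDING_POINT: the Michael-acceptor beta-carbon (terminal
    alkene carbon) of a matched warhead.
    """
    feats: list[tuple[FeatureType, np.ndarray]] = []
    for a in mol.GetAtoms():
        z = a.GetAtomicNum()
        if z not in (7, 8):
            continue
        pos = coords[a.GetIdx()]
        if a.GetTotalNumHs(includeNeighbors=True) > 0:
            feats.append((FeatureType.HBD, pos))
        if z == 8:
            feats.append((FeatureType.HBA, pos))
        elif (a.GetFormalCharge() <= 0 and a.GetDegree() < 4
              and not (a.GetIsAromatic() and a.GetTotalNumHs(includeNeighbors=True) > 0)):
            feats.append((FeatureType.HBA, pos))
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            feats.append((FeatureType.AROMATIC, coords[list(ring)].mean(axis=0)))
    for comp in _hydrophobic_components(mol):
        feats.append((FeatureType.HYDROPHOBIC, coords[comp].mean(axis=0)))
    if warhead is not None:
        match = mol.GetSubstructMatch(warhead.query())
        if match:
            feats.append((FeatureType.RESIDUE_BONDING_POINT, coords[match[0]]))
    return feats


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid motion (R, t) minimizing ||R P + t - Q||; P, Q are (n, 3)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def _group_assignments(slots: list[tuple[int, bool]], cands: list[int]):
    """Injective mappings for one feature type.

    ``slots`` are (model-feature index, optional) pairs; yields tuples of
    candidate indices (or None for skipped optional slots) in a fixed,
    identity-first order.
    """
    def rec(pos, used):
        if pos == len(slots):
            yield ()
            return
        _, optional = slots[pos]
        for c in cands:
            if c in used:
                continue
            for rest in rec(pos + 1, used | {c}):
                yield (c,) + rest
        if optional:
            for rest in rec(pos + 1, used):
                yield (None,) + rest

    yield from rec(0, frozenset())


def _model_assignments(model: PharmacophoreModel,
                       cand: list[tuple[FeatureType, np.ndarray]],
                       max_assignments: int):
    """Injective assignments model-feature -> candidate-feature index.

    Required features must be assigned; optional features may be skipped
    (None). Enumeration is injective by construction (no post-filtering),
    deterministic, identity-first, and truncated at the cap.
    """
    groups: dict[FeatureType, list[tuple[int, bool]]] = {}
    for k, f in enumerate(model.features):
        groups.setdefault(f.type, []).append((k, f.optional))
    per_group = []
    for ftype, slots in groups.items():
        cands = [i for i, (t, _) in enumerate(cand) if t == ftype]
        opts = list(itertools.islice(_group_assignments(slots, cands),
                                     max_assignments))
        if not opts:
            return  # a required slot of this type has no candidate
        per_group.append((slots, opts))
    count = 0
    for combo in itertools.product(*(opts for _, opts in per_group)):
        assignment: list[int | None] = [None] * len(model.features)
        for (slots, _), chosen in zip(per_group, combo):
            for (k, _opt), c in zip(slots, chosen):
                assignment[k] = c
        if all(c is None for c in assignment):
            continue
        yield tuple(assignment)
        count += 1
        if count >= max_assignments:
            return


def fit(conformers: ConformerSet, model: PharmacophoreModel,
        warhead: WarheadPattern | None = None,
        max_assignments: int = 2000) -> FitResult:
    """Best pharmacophore fit of a conformer ensemble against *model*."""
    heavy_idx = [a.GetIdx() for a in conformers.molecule.GetAtoms()
                 if a.GetAtomicNum() > 1]
    n_feat = len(model.features)
    best = FitResult(best_score=0.0, matched_features=0, rmsd=float("inf"),
                     conformer_index=-1, clash=False, fit=False)
    excl_pos = np.array([e.position for e in model.exclusion_volumes]).reshape(-1, 3)
    excl_rad = np.array([e.radius for e in model.exclusion_volumes])
    model_pos = np.array([f.position for f in model.features])
    for ci, coords in enumerate(conformers.conformers):
        cand = perceive_features(conformers.molecule, coords, warhead)
        for combo in _model_assignments(model, cand, max_assignments):
            pairs = [(k, c) for k, c in enumerate(combo) if c is not None]
            P = np.array([cand[c][1] for _, c in pairs])
            Q = np.array([model_pos[k] for k, _ in pairs])
            R, t = _kabsch(P, Q)
            moved = P @ R.T + t
            dists = np.linalg.norm(moved - Q, axis=1)
            matched = [
                (k, d) for (k, _), d in zip(pairs, dists)
                if d <= model.features[k].radius
            ]
            if not matched:
                continue
            req_matched = {k for k, _ in matched if not model.features[k].optional}
            all_req = len(req_matched) == len(model.required)
            clash = False
            if len(excl_pos):
                atoms = coords[heavy_idx] @ R.T + t
                dmat = np.linalg.norm(atoms[:, None, :] - excl_pos[None, :, :], axis=2)
                clash = bool((dmat < excl_rad[None, :]).any())
            if clash:
                continue
            mdists = np.array([d for _, d in matched])
            score = float(np.exp(-mdists / 2.0).sum() / n_feat)
            rmsd = float(np.sqrt((mdists ** 2).mean()))
            if score > best.best_score:
                best = FitResult(best_score=score, matched_features=len(matched),
                                 rmsd=rmsd, conformer_index=ci, clash=False,
                                 fit=all_req)
    if best.conformer_index < 0 and model.exclusion_volumes:
        # nothing scoreable; report whether clashes were the cause
        best.clash = _always_clashes(conformers, model, heavy_idx, warhead, max_assignments)
    return best


def _always_clashes(conformers, model, heavy_idx, warhead, max_assignments) -> bool:
    excl_pos = np.array([e.position for e in model.exclusion_volumes]).reshape(-1, 3)
    excl_rad = np.array([e.radius for e in model.exclusion_volumes])
    model_pos = np.array([f.position for f in model.features])
    saw_assignment = False
    for coords in conformers.conformers:
        cand = perceive_features(conformers.molecule, coords, warhead)
        for combo in _model_assignments(model, cand, max_assignments):
            saw_assignment = True
            pairs = [(k, c) for k, c in enumerate(combo) if c is not None]
            P = np.array([cand[c][1] for _, c in pairs])
            Q = np.array([model_pos[k] for k, _ in pairs])
            R, t = _kabsch(P, Q)
            atoms = coords[heavy_idx] @ R.T + t
            dmat = np.linalg.norm(atoms[:, None, :] - excl_pos[None, :, :], axis=2)
            if not (dmat < excl_rad[None, :]).any():
                return False
    return saw_assignment


def model_from_conformer(mol: Chem.Mol, coords: np.ndarray,
                         radius: float = 1.5,
                         warhead: WarheadPattern | None = None,
                         types: set[FeatureType] | None = None,
                         max_features: int | None = None) -> PharmacophoreModel:
    """Build a model directly from one conformer's perceived features
    (the way reference models are derived from a bound ligand pose)."""
    feats = perceive_features(mol, coords, warhead)
    if types is not None:
        feats = [f for f in feats if f[0] in types]
    if max_features is not None:
        feats = feats[:max_features]
    if not feats:
        raise CovgenError("no perceivable features for model construction")
    return PharmacophoreModel(
        features=tuple(Feature(t, tuple(map(float, p)), radius) for t, p in feats)
    )
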