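"""Chemical-space projection: circular fingerprints + PCA.

Molecules are encoded as 2048-bit extended-connectivity fingerprints with
bond diameter six (ECFP6, Morgan radius 3) and projected onto the first
two principal components of the mean-centered bit matrix. The sign of each
component is fixed by making its largest-magnitude loading positive, so
projections are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator
from sklearn.decomposition import PCA

from .chem import Molecule, mol_from_smiles
from .errors import DegenerateInputError

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)


@dataclass
class FingerprintMatrix:
    ids: list[str]
    bits: np.ndarray  # (n, 2048) uint8


@dataclass
class Projection:
    coordinates: np.ndarray  # (n, 2)
    explained_variance: tuple[float, float]
    labels: list[str]


def fingerprint(mols: Sequence[Molecule]) -> FingerprintMatrix:
    """ECFP6/2048 bit vectors; identical molecules give identical rows."""
    bits = np.zeros((len(mols), 2048), dtype=np.uint8)
    ids = []
    for i, m in enumerate(mols):
        fp = _FP_GEN.GetFingerprint(mol_from_smiles(m.smiles))
        bits[i, list(fp.GetOnBits())] = 1
        ids.append(m.id)
    return FingerprintMatrix(ids=ids, bits=bits)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    return inter / union if union else 0.0


def project(fp: FingerprintMatrix, labels: Sequence[str] | None = None) -> Projection:
    """Mean-centered PCA onto the first two components."""
    if fp.bits.shape[0] < 3:
        raise ValueError("PCA projection needs at least 3 molecules")
    X = fp.bits.astype(float)
    if np.allclose(X, X[0]):
        raise DegenerateInputError("all fingerprints identical; nothing to project")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(2):
        k = int(np.abs(pca.components_[j]).argmax())
        if pca.components_[j, k] < 0:
            coords[:, j] *= -1
    ev = pca.explained_variance_ratio_
    return Projection(
        coordinates=coords,
        explained_variance=(float(ev[0]), float(ev[1])),
        labels=list(labels) if labels is not None else list(fp.ids),
    )


def mean_intragroup_distance(proj: Projection, group: str) -> float:
    """Mean pairwise Euclidean distance in PC1/PC2 within one label group."""
    pts = proj.coordinates[[i for i, g in enumerate(proj.labels) if g == group]]
    if len(pts) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 members")
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    iu = np.triu_indices(len(pts), k=1)
    return float(d[iu].mean())
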