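"""Deterministic synthetic compound libraries for every pipeline stage.

The generator emulates, at desk scale, the data situation of a kinome-wide
pre-training collection plus a small covalent fine-tuning set: a
combinatorial library of hinge-binder-like heteroaromatic cores (Key 2
scaffolds with the two attachment sites), N-acyl azacycle Value 2
fragments (a piperidine acrylamide warhead, near-miss ring variants, and a
saturated decoy), and a pool of (hetero)aryl/aliphatic Value 1
substituents. The fine-tune subset contains only warhead-bearing compounds
drawn from at most three scaffolds, mirroring a target-focused covalent
inhibitor series. Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import assemble_compound, assemble_key1
from .chem import Fragment, Molecule, Role, WarheadPattern, matches_warhead
from .errors import ConfigError

#: hinge-binder-like cores; [At] = Value 1 site, [*:1] = Value 2 site
SCAFFOLDS: tuple[str, ...] = (
    "Nc1ncnc2c1c([At])nn2[*:1]",      # 4-aminopyrazolo[3,4-d]pyrimidine (ibrutinib-like)
    "Nc1ncnc2c1c([At])cn2[*:1]",      # 7-deazaadenine
    "Nc1ncnc2c1nc([At])n2[*:1]",      # adenine
    "c1ccc2c(c1)nc([At])n2[*:1]",     # benzimidazole
    "c1ccc2c(c1)c([At])nn2[*:1]",     # indazole
    "Nc1nc([At])nc2cc([*:1])ccc12",   # 4-aminoquinazoline, C-linked Value 2
    "O=c1[nH]cnc2c1c([At])cn2[*:1]",  # 7-deazahypoxanthine
    "Nc1ncnc2sc([At])c([*:1])c12",    # thieno[2,3-d]pyrimidine
)

#: Value 2 pool: two warhead-bearing piperidine acrylamides, a pyrrolidine
#: near-miss, the saturated (non-Michael-acceptor) decoy, and an acyclic amide
VALUE2_POOL: tuple[str, ...] = (
    "*C1CCCN(C(=O)C=C)C1",   # piperidin-3-yl acrylamide (warhead)
    "*C1CCN(C(=O)C=C)CC1",   # piperidin-4-yl acrylamide (warhead)
    "*C1CCN(C(=O)C=C)C1",    # pyrrolidine acrylamide (ring too small)
    "*C1CCCN(C(=O)CC)C1",    # saturated propanamide decoy
    "*CCN(C)C(=O)C=C",       # acyclic acrylamide
)

DECOY_VALUE2 = "*C1CCCN(C(=O)CC)C1"

_ARYL_GROUPS = ("F", "Cl", "Br", "C", "CC", "OC", "N", "O", "C#N",
                "C(F)(F)F", "OCC", "Oc2ccccc2", "N(C)C")

#: aryl/aliphatic substituent pool for the Value 1 site
VALUE1_POOL: tuple[str, ...] = (
    tuple(f"*c1ccc({g})cc1" for g in _ARYL_GROUPS)
    + tuple(f"*c1cccc({g})c1" for g in _ARYL_GROUPS)
    + ("*c1ccccc1", "*c1cccnc1", "*CC1CCOCC1", "*c1ccc(CN2CCOCC2)cc1")
)

IBRUTINIB_SMILES = "C=CC(=O)N1CCCC(n2nc(-c3ccc(Oc4ccccc4)cc3)c3c(N)ncnc32)C1"
IBRUTINIB_KEY2 = "Nc1ncnc2c1c([At])nn2[*:1]"
IBRUTINIB_VALUE2 = "*C1CCCN(C(=O)C=C)C1"
IBRUTINIB_VALUE1 = "*c1ccc(Oc2ccccc2)cc1"


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the synthetic library.

    Defaults give roughly a thousand pre-training compounds (8 scaffolds x
    5 Value 2 x 30 Value 1 at 80% series fill) and a 34-compound warhead
    fine-tune subset on two scaffolds, echoing the scale relationship of a
    kinome collection versus a single covalent inhibitor series.
    """

    n_scaffolds: int = len(SCAFFOLDS)
    n_value2_pool: int = len(VALUE2_POOL)
    n_value1_pool: int = len(VALUE1_POOL)
    series_completeness: float = 0.8
    n_finetune: int = 34
    n_finetune_scaffolds: int = 2
    seed: int = 7

    def __post_init__(self):
        if min(self.n_scaffolds, self.n_value2_pool, self.n_value1_pool,
               self.n_finetune, self.n_finetune_scaffolds) <= 0:
            raise ConfigError("all fixture counts must be positive")
        if not (0 < self.series_completeness <= 1):
            raise ConfigError("series_completeness must be in (0, 1]")
        if self.n_scaffolds > len(SCAFFOLDS):
            raise ConfigError(f"at most {len(SCAFFOLDS)} scaffolds available")
        if self.n_value2_pool > len(VALUE2_POOL):
            raise ConfigError(f"at most {len(VALUE2_POOL)} Value 2 fragments available")
        if self.n_value1_pool > len(VALUE1_POOL):
            raise ConfigError(f"at most {len(VALUE1_POOL)} Value 1 fragments available")
        if self.n_finetune_scaffolds > 3:
            raise ConfigError("fine-tune subset is limited to 3 scaffolds")


def _fragments(spec: FixtureSpec):
    scaffolds = [Fragment.from_smiles(s, Role.KEY2) for s in SCAFFOLDS[:spec.n_scaffolds]]
    value2s = [Fragment.from_smiles(s, Role.VALUE2) for s in VALUE2_POOL[:spec.n_value2_pool]]
    value1s = [Fragment.from_smiles(s, Role.VALUE1) for s in VALUE1_POOL[:spec.n_value1_pool]]
    return scaffolds, value2s, value1s


def generate_library(spec: FixtureSpec = FixtureSpec()) -> tuple[list[Molecule], list[Molecule]]:
    """Build the (pretrain, finetune) molecule lists, fully seeded.

    Each scaffold's combinatorial Value2 x Value1 series is subsampled to
    exactly ``round(series_completeness * n_cells)`` compounds. The
    fine-tune subset is drawn from the warhead-bearing combinations of the
    first ``n_finetune_scaffolds`` scaffolds.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds, value2s, value1s = _fragments(spec)
    warhead = WarheadPattern()

    pretrain: list[Molecule] = []
    idx = 0
    for scaffold in scaffolds:
        cells = [(v2, v1) for v2 in value2s for v1 in value1s]
        n_keep = max(1, int(round(spec.series_completeness * len(cells))))
        keep = sorted(rng.choice(len(cells), size=n_keep, replace=False))
        key1_cache: dict[str, Fragment] = {}
        for c in keep:
            v2, v1 = cells[c]
            if v2.smiles not in key1_cache:
                key1_cache[v2.smiles] = assemble_key1(scaffold, v2)
            mol = assemble_compound(key1_cache[v2.smiles], v1)
            idx += 1
            pretrain.append(Molecule.from_smiles(mol.smiles, f"P{idx:05d}"))

    warhead_v2 = [v2 for v2 in value2s if matches_warhead(v2, warhead)]
    if not warhead_v2:
        raise ConfigError("Value 2 pool contains no warhead-bearing fragment")
    eligible = [
        (s, v2, v1)
        for s in scaffolds[:spec.n_finetune_scaffolds]
        for v2 in warhead_v2
        for v1 in value1s
    ]
    if spec.n_finetune > len(eligible):
        raise ConfigError(
            f"fine-tune size {spec.n_finetune} exceeds the {len(eligible)} "
            "eligible warhead-bearing combinations"
        )
    chosen = sorted(rng.choice(len(eligible), size=spec.n_finetune, replace=False))
    finetune = []
    for rank, c in enumerate(chosen, start=1):
        s, v2, v1 = eligible[c]
        mol = assemble_compound(assemble_key1(s, v2), v1)
        finetune.append(Molecule.from_smiles(mol.smiles, f"F{rank:03d}"))
    return pretrain, finetune


def ibrutinib_fixture() -> tuple[Molecule, Fragment, Fragment, Fragment]:
    """Ibrutinib (C25H24N6O2) and its canonical Key 2 / Value 2 / Value 1
    decomposition; the worked reference example of the cutting scheme."""
    mol = Molecule.from_smiles(IBRUTINIB_SMILES, "ibrutinib")
    key2 = Fragment.from_smiles(IBRUTINIB_KEY2, Role.KEY2)
    value2 = Fragment.from_smiles(IBRUTINIB_VALUE2, Role.VALUE2)
    value1 = Fragment.from_smiles(IBRUTINIB_VALUE1, Role.VALUE1)
    return mol, key2, value2, value1
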