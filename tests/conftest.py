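"""Shared fixtures: reference molecules, synthetic libraries, toy generators."""

from __future__ import annotations

import pytest

from covgen.chem import Fragment, Role, WarheadPattern
from covgen.fixtures import FixtureSpec, generate_library, ibrutinib_fixture
from covgen.fragmentation import FragmentationConfig
from covgen.seq2seq import TrainConfig, train


@pytest.fixture(scope="session")
def warhead() -> WarheadPattern:
    return WarheadPattern()


@pytest.fixture(scope="session")
def frag_config(warhead) -> FragmentationConfig:
    return FragmentationConfig(warhead=warhead)


@pytest.fixture(scope="session")
def ibrutinib():
    """(molecule, key2, value2, value1) reference decomposition."""
    return ibrutinib_fixture()


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(n_scaffolds=3, n_value2_pool=4, n_value1_pool=6,
                       series_completeness=1.0, n_finetune=8, seed=11)


@pytest.fixture(scope="session")
def small_library(small_spec):
    """A fully occupied 3x4x6 combinatorial library plus its fine-tune subset."""
    return generate_library(small_spec)


@pytest.fixture(scope="session")
def full_library():
    """The default ~1000-compound library used for the heavier checks."""
    return generate_library(FixtureSpec())


KEY2_CYCLE = [
    "Nc1ncnc2c1c([At])nn2[*:1]",
    "Nc1ncnc2c1c([At])cn2[*:1]",
    "Nc1ncnc2c1nc([At])n2[*:1]",
    "[At]c1nc2ccccc2n1[*:1]",
    "[At]c1nn([*:1])c2ccccc12",
]


@pytest.fixture(scope="session")
def memorization_pairs():
    """Five Key 2 -> Key 2 pairs forming a cycle over fixture scaffolds."""
    frags = [Fragment.from_smiles(s, Role.KEY2) for s in KEY2_CYCLE]
    return [(frags[i], frags[(i + 1) % len(frags)]) for i in range(len(frags))]


@pytest.fixture(scope="session")
def overfit_model(memorization_pairs):
    """A compact generator trained to memorization on five pairs."""
    config = TrainConfig(latent_dim=64, embedding_dim=32, seed=3,
                         learning_rate=5e-3, split_ratio=0.99)
    return train(memorization_pairs, config, "pretrain", kind=Role.KEY2, epochs=500)
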