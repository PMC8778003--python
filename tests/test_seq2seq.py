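"""Tokenizer, training-pair harvesting, training, sampling, novelty scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covgen.assembly import assemble_compound, assemble_key1, cumulative_score
from covgen.chem import Fragment, Molecule, Role
from covgen.errors import CovgenError, VocabularyError
from covgen.fixtures import IBRUTINIB_KEY2, VALUE1_POOL, VALUE2_POOL
from covgen.fragmentation import build_sarms
from covgen.seq2seq import (
    Tokenizer,
    TrainConfig,
    greedy_decode,
    make_training_pairs,
    novelty_score,
    sample,
    train,
)
from tests.conftest import KEY2_CYCLE


class TestTokenizer:
    @given(st.sampled_from(VALUE1_POOL + VALUE2_POOL + tuple(KEY2_CYCLE)))
    @settings(derandomize=True, max_examples=40)
    def test_roundtrip(self, smiles):
        tok = Tokenizer.from_corpus([smiles])
        assert tok.decode(tok.encode(smiles)) == smiles

    def test_multicharacter_tokens_stay_atomic(self):
        toks = Tokenizer.split("Clc1ccc(Br)cc1[At]%10C[*:1]")
        assert "Cl" in toks and "Br" in toks and "[At]" in toks
        assert "[*:1]" in toks and "%10" in toks

    def test_out_of_vocabulary_raises_with_tokens(self):
        tok = Tokenizer.from_corpus(["CCO"])
        with pytest.raises(VocabularyError, match="Br"):
            tok.encode("CCBr")


@pytest.fixture(scope="module")
def two_by_two_sarm(frag_config):
    key2 = Fragment.from_smiles(IBRUTINIB_KEY2, Role.KEY2)
    v2s = ["*C1CCCN(C(=O)C=C)C1", "*C1CCN(C(=O)C=C)CC1"]
    v1s = ["*c1ccccc1", "*c1ccc(F)cc1"]
    mols = []
    for i, v2 in enumerate(v2s):
        for j, v1 in enumerate(v1s):
            m = assemble_compound(
                assemble_key1(key2, Fragment.from_smiles(v2, Role.VALUE2)),
                Fragment.from_smiles(v1, Role.VALUE1))
            mols.append(Molecule.from_smiles(m.smiles, f"c{i}{j}"))
    sarms = build_sarms(mols, frag_config)
    return key2, [m for m in sarms if m.key2.smiles == key2.smiles][0], sarms


class TestTrainingPairs:
    def test_value2_pairs_one_per_row(self, two_by_two_sarm):
        _, matrix, _ = two_by_two_sarm
        pairs = make_training_pairs([matrix], Role.VALUE2)
        assert len(pairs) == 2
        assert all(i.role is Role.KEY2 and o.role is Role.VALUE2 for i, o in pairs)

    def test_value1_pairs_one_per_cell(self, two_by_two_sarm):
        _, matrix, _ = two_by_two_sarm
        pairs = make_training_pairs([matrix], Role.VALUE1)
        assert len(pairs) == 4
        assert all(i.role is Role.KEY1 and o.role is Role.VALUE1 for i, o in pairs)

    def test_key2_needs_related_series(self, two_by_two_sarm):
        _, matrix, sarms = two_by_two_sarm
        assert make_training_pairs([matrix], Role.KEY2) == []
        # the full index contains alternative cores sharing Value 1 columns,
        # and every pair appears in both directions
        pairs = make_training_pairs(sarms, Role.KEY2)
        pair_keys = {(i.smiles, o.smiles) for i, o in pairs}
        assert pair_keys and all((b, a) in pair_keys for a, b in pair_keys)

    def test_empty_input_raises(self):
        with pytest.raises(CovgenError):
            make_training_pairs([], Role.VALUE2)


def _toy_pairs(n=50, seed=0):
    rng = np.random.default_rng(seed)
    v1 = [Fragment.from_smiles(s, Role.VALUE1) for s in VALUE1_POOL]
    idx = rng.integers(0, len(v1), size=(n, 2))
    return [(v1[i], v1[j]) for i, j in idx]


class TestTrain:
    def test_loss_decreases_on_small_corpus(self):
        """Training converges: train loss non-increasing over the last three
        epochs in at least two of three restarts, validation loss finite."""
        good = 0
        for seed in range(3):
            cfg = TrainConfig(latent_dim=48, embedding_dim=24, seed=seed,
                              learning_rate=5e-3)
            model = train(_toy_pairs(50, seed), cfg, "pretrain",
                          kind=Role.VALUE1, epochs=5)
            losses = [e["train_loss"] for e in model.training_log]
            assert np.isfinite(model.training_log[-1]["val_loss"])
            if losses[-1] <= losses[-2] <= losses[-3]:
                good += 1
        assert good >= 2

    def test_empty_pairs_error(self):
        with pytest.raises(CovgenError):
            train([], TrainConfig(), "pretrain", kind=Role.VALUE1)

    def test_finetune_requires_base(self):
        with pytest.raises(ValueError):
            train(_toy_pairs(5), TrainConfig(), "finetune")

    def test_finetune_vocabulary_error_names_token(self, overfit_model):
        alien = [(Fragment.from_smiles("*[Se]CC", Role.VALUE1),) * 2]
        with pytest.raises(VocabularyError, match=r"\[Se\]"):
            train(alien, TrainConfig(), "finetune", base=overfit_model)

    def test_overfit_memorizes_all_pairs(self, overfit_model, memorization_pairs):
        for inp, out in memorization_pairs:
            assert greedy_decode(overfit_model, inp) == out.smiles


class TestSample:
    def test_zero_n_rejected(self, overfit_model, memorization_pairs):
        with pytest.raises(ValueError):
            sample(overfit_model, memorization_pairs[0][0], 0, 1.0, 1)

    def test_near_zero_temperature_recovers_greedy(self, overfit_model,
                                                   memorization_pairs):
        inp, out = memorization_pairs[0]
        res = sample(overfit_model, inp, 1, temperature=0.01, seed=9)
        assert [g.fragment.smiles for g in res.fragments] == [out.smiles]

    def test_seed_determinism(self, overfit_model, memorization_pairs):
        inp = memorization_pairs[0][0]
        a = sample(overfit_model, inp, 100, 1.5, seed=4)
        b = sample(overfit_model, inp, 100, 1.5, seed=4)
        assert [g.fragment.smiles for g in a.fragments] == \
               [g.fragment.smiles for g in b.fragments]
        assert [g.score for g in a.fragments] == [g.score for g in b.fragments]

    def test_temperature_increases_diversity(self, overfit_model, memorization_pairs):
        inp = memorization_pairs[0][0]
        wins = sum(
            len(sample(overfit_model, inp, 200, 2.0, seed=s).fragments)
            >= len(sample(overfit_model, inp, 200, 0.5, seed=s).fragments)
            for s in range(5)
        )
        assert wins >= 4

    def test_emissions_are_role_valid(self, overfit_model, memorization_pairs):
        res = sample(overfit_model, memorization_pairs[0][0], 150, 2.0, seed=2)
        for g in res.fragments:
            assert g.fragment.role is Role.KEY2
            assert "[At]" in g.fragment.smiles and "[*:1]" in g.fragment.smiles
        assert res.n_requested == len(res.fragments) + res.n_invalid \
            + res.n_duplicate


class TestNoveltyScore:
    def test_memorized_outputs_score_near_zero(self, overfit_model,
                                               memorization_pairs):
        for inp, out in memorization_pairs:
            assert novelty_score(overfit_model, inp, out) < 0.1

    def test_bounds_on_many_outputs(self, overfit_model, memorization_pairs):
        res = sample(overfit_model, memorization_pairs[0][0], 1000, 2.5, seed=0)
        assert res.fragments and all(0.0 <= g.score <= 1.0 for g in res.fragments)

    def test_training_outputs_score_below_novel_ones(self, overfit_model,
                                                     memorization_pairs):
        inp = memorization_pairs[0][0]
        train_smiles = {out.smiles for _, out in memorization_pairs}
        wins = 0
        for s in range(5):
            res = sample(overfit_model, inp, 300, 2.0, seed=s)
            known = [g.score for g in res.fragments if g.fragment.smiles in train_smiles]
            novel = [g.score for g in res.fragments if g.fragment.smiles not in train_smiles]
            if known and novel and np.mean(known) < np.mean(novel):
                wins += 1
        assert wins >= 4

    def test_cumulative_score_is_clipped_mean(self):
        assert cumulative_score(0.1, 0.2, 0.6) == pytest.approx(0.3)
        assert cumulative_score(0.0, 0.0, 0.0) == 0.0
        assert cumulative_score(1.0, 1.0, 1.0) == 1.0
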