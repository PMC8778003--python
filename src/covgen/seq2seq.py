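"""The three fragment generators (Key 2, Value 2, Value 1).

Each generator is a sequence-to-sequence LSTM encoder-decoder over SMILES
tokens. A generator is first pre-trained on fragment pairs harvested from
the SAR matrices of a large library, then fine-tuned (resuming from the
pre-trained weights) on the matrices of a small target-focused set. New
fragments are sampled token-by-token from ``softmax(logits / T)`` with a
temperature factor T, and every emission carries a novelty score

    s = 1 - exp(mean per-token log-probability)   in [0, 1],

which is ~0 for fragments the model reproduces with probability ~1 (i.e.
fragments like the training data) and approaches 1 for improbable, novel
fragments. The cumulative score of an assembled candidate is the mean of
its three fragment scores.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .assembly import assemble_key1
from .chem import Fragment, Role
from .errors import AttachmentGrammarError, CovgenError, InvalidStructureError, VocabularyError
from .fragmentation import SARMatrix

PAD, BOS, EOS = "<pad>", "<s>", "</s>"

_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")

#: output fragment role produced by each generator kind
KIND_ROLE = {Role.KEY2: Role.KEY2, Role.VALUE2: Role.VALUE2, Role.VALUE1: Role.VALUE1}


@dataclass(frozen=True)
class Tokenizer:
    """SMILES tokenizer with multi-character tokens ([At], [*:1], Cl, Br,
    bracket atoms, %nn ring closures) and pad/start/end symbols."""

    vocabulary: tuple[str, ...]
    max_length: int = 120

    @classmethod
    def from_corpus(cls, smiles_iter, max_length: int = 120) -> "Tokenizer":
        tokens: set[str] = set()
        for s in smiles_iter:
            tokens.update(cls.split(s))
        return cls(vocabulary=(PAD, BOS, EOS) + tuple(sorted(tokens)),
                   max_length=max_length)

    @staticmethod
    def split(smiles: str) -> list[str]:
        toks = _TOKEN_RE.findall(smiles)
        if "".join(toks) != smiles:
            raise VocabularyError([smiles], "untokenizable SMILES")
        return toks

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def bos_id(self) -> int:
        return 1

    @property
    def eos_id(self) -> int:
        return 2

    def __len__(self) -> int:
        return len(self.vocabulary)

    def _index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.vocabulary)}

    def encode(self, smiles: str) -> list[int]:
        index = self._index()
        toks = self.split(smiles)
        missing = [t for t in toks if t not in index]
        if missing:
            raise VocabularyError(missing)
        return [index[t] for t in toks]

    def decode(self, ids) -> str:
        out = []
        for i in ids:
            tok = self.vocabulary[int(i)]
            if tok == EOS:
                break
            if tok in (PAD, BOS):
                continue
            out.append(tok)
        return "".join(out)

    def covers(self, smiles: str) -> bool:
        index = self._index()
        try:
            return all(t in index for t in self.split(smiles))
        except VocabularyError:
            return False


@dataclass
class TrainConfig:
    """Training schedule. Epoch defaults are the published schedule
    (pre-train 30/10/30, fine-tune 50/500/500 for Key 2/Value 2/Value 1);
    batch 64, 9:1 train/validation split, 256-dimensional latent state."""

    pretrain_epochs: dict[Role, int] = field(default_factory=lambda: {
        Role.KEY2: 30, Role.VALUE2: 10, Role.VALUE1: 30})
    finetune_epochs: dict[Role, int] = field(default_factory=lambda: {
        Role.KEY2: 50, Role.VALUE2: 500, Role.VALUE1: 500})
    batch_size: int = 64
    split_ratio: float = 0.9
    seed: int = 0
    latent_dim: int = 256
    embedding_dim: int = 64
    learning_rate: float = 2e-3
    max_length: int = 120
    clip_norm: float = 5.0

    def __post_init__(self):
        if not (0 < self.split_ratio <= 1):
            raise ValueError("split_ratio must be in (0, 1]")
        for d in (self.pretrain_epochs, self.finetune_epochs):
            if any(v <= 0 for v in d.values()):
                raise ValueError("epoch counts must be positive")

    def epochs_for(self, kind: Role, stage: str) -> int:
        table = self.pretrain_epochs if stage == "pretrain" else self.finetune_epochs
        return table[kind]


@dataclass
class GeneratorModel:
    """A trained fragment generator with its tokenizer and training log."""

    kind: Role
    tokenizer: Tokenizer
    params: dict[str, np.ndarray]
    latent_dim: int
    embedding_dim: int
    training_log: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        meta = {
            "kind": self.kind.value,
            "vocabulary": list(self.tokenizer.vocabulary),
            "max_length": self.tokenizer.max_length,
            "latent_dim": self.latent_dim,
            "embedding_dim": self.embedding_dim,
            "training_log": self.training_log,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(
            kind=Role(meta["kind"]),
            tokenizer=Tokenizer(tuple(meta["vocabulary"]), meta["max_length"]),
            params=params,
            latent_dim=meta["latent_dim"],
            embedding_dim=meta["embedding_dim"],
            training_log=meta["training_log"],
        )


@dataclass(frozen=True)
class GeneratedFragment:
    """A sampled fragment with its novelty score and the input it came from."""

    fragment: Fragment
    score: float
    source_input: Fragment


@dataclass
class SampleResult:
    """Unique valid fragments plus discard statistics for one sampling run."""

    fragments: list[GeneratedFragment]
    n_requested: int
    n_unparseable: int
    n_role_invalid: int
    n_duplicate: int

    @property
    def n_invalid(self) -> int:
        return self.n_unparseable + self.n_role_invalid

    @property
    def parse_rate(self) -> float:
        """Fraction of raw emissions that parse as SMILES."""
        return 1.0 - self.n_unparseable / max(self.n_requested, 1)


def make_training_pairs(sarms: list[SARMatrix], kind: Role) -> list[tuple[Fragment, Fragment]]:
    """Harvest (input, output) fragment pairs from SAR matrices.

    VALUE2: (Key 2, Value 2) from occupied cells. VALUE1: (Key 1, Value 1)
    from occupied cells, the Key 1 re-assembled from the matrix's Key 2 and
    the cell's Value 2 row. KEY2: ordered pairs of distinct Key 2 cores
    whose matrices share at least one Value 1 column (related series), both
    directions. All pair lists are deduplicated and sorted.
    """
    if not sarms:
        raise CovgenError("no SAR matrices: insufficient data for training pairs")
    pairs: dict[tuple[str, str], tuple[Fragment, Fragment]] = {}
    if kind is Role.VALUE2:
        for m in sarms:
            for (i, _j) in m.cells:
                pairs[(m.key2.smiles, m.rows[i].smiles)] = (m.key2, m.rows[i])
    elif kind is Role.VALUE1:
        for m in sarms:
            key1_cache: dict[int, Fragment] = {}
            for (i, j) in m.cells:
                if i not in key1_cache:
                    key1_cache[i] = assemble_key1(m.key2, m.rows[i])
                k1 = key1_cache[i]
                pairs[(k1.smiles, m.columns[j].smiles)] = (k1, m.columns[j])
    elif kind is Role.KEY2:
        col_sets = [(m.key2, {c.smiles for c in m.columns}) for m in sarms]
        for a, (k2a, cols_a) in enumerate(col_sets):
            for b, (k2b, cols_b) in enumerate(col_sets):
                if a == b or k2a.smiles == k2b.smiles:
                    continue
                if cols_a & cols_b:
                    pairs[(k2a.smiles, k2b.smiles)] = (k2a, k2b)
    else:
        raise ValueError(f"unsupported generator kind {kind!r}")
    return [pairs[k] for k in sorted(pairs)]


def _encode_batch(tokenizer: Tokenizer, seqs: list[list[int]], extra: int = 0):
    """Right-pad to a (B, T) id array plus float mask."""
    T = max(len(s) for s in seqs) + extra
    ids = np.full((len(seqs), T), tokenizer.pad_id, dtype=np.int64)
    mask = np.zeros((len(seqs), T))
    for r, s in enumerate(seqs):
        ids[r, :len(s)] = s
        mask[r, :len(s)] = 1.0
    return ids, mask


def _prepare_pairs(tokenizer: Tokenizer, pairs):
    enc, dec_in, dec_tgt = [], [], []
    for inp, out in pairs:
        e = tokenizer.encode(inp.smiles)
        d = tokenizer.encode(out.smiles)
        if len(e) > tokenizer.max_length or len(d) + 1 > tokenizer.max_length:
            continue
        enc.append(e)
        dec_in.append([tokenizer.bos_id] + d)
        dec_tgt.append(d + [tokenizer.eos_id])
    if not enc:
        raise CovgenError("no pair fits within max_length")
    return enc, dec_in, dec_tgt


def _batch_loss(model: GeneratorModel, enc, dec_in, dec_tgt, idx):
    tok = model.tokenizer
    e_ids, e_mask = _encode_batch(tok, [enc[i] for i in idx])
    d_in, d_mask = _encode_batch(tok, [dec_in[i] for i in idx])
    d_tgt, _ = _encode_batch(tok, [dec_tgt[i] for i in idx])
    logp, _, _, _ = nn.seq2seq_forward(model.params, e_ids, e_mask, d_in, d_mask)
    B, S = d_tgt.shape
    rows = np.arange(B)[:, None]
    cols = np.arange(S)[None, :]
    n_tok = max(d_mask.sum(), 1.0)
    return float(-(logp[rows, cols, d_tgt] * d_mask).sum() / n_tok)


def train(
    pairs: list[tuple[Fragment, Fragment]],
    config: TrainConfig,
    stage: str = "pretrain",
    base: GeneratorModel | None = None,
    kind: Role | None = None,
    epochs: int | None = None,
) -> GeneratorModel:
    """Train a generator on fragment pairs.

    Pre-training builds the tokenizer from the corpus and initializes fresh
    parameters; fine-tuning resumes from ``base`` and raises
    :class:`VocabularyError` if the fine-tune corpus contains tokens outside
    the pre-trained vocabulary. Reproducible for a fixed ``config.seed``.
    """
    if stage not in ("pretrain", "finetune"):
        raise ValueError(f"unknown stage {stage!r}")
    if not pairs:
        raise CovgenError("empty training pair list")
    rng = np.random.default_rng(config.seed)

    if stage == "finetune":
        if base is None:
            raise ValueError("finetune requires a base model")
        model = GeneratorModel(
            kind=base.kind, tokenizer=base.tokenizer,
            params={k: v.copy() for k, v in base.params.items()},
            latent_dim=base.latent_dim, embedding_dim=base.embedding_dim,
            training_log=copy.deepcopy(base.training_log),
        )
        missing: list[str] = []
        for inp, out in pairs:
            for s in (inp.smiles, out.smiles):
                for t in Tokenizer.split(s):
                    if t not in model.tokenizer.vocabulary:
                        missing.append(t)
        if missing:
            raise VocabularyError(missing, "fine-tune data outside pre-trained vocabulary")
    else:
        if kind is None:
            raise ValueError("pretrain requires the generator kind")
        corpus = [s for inp, out in pairs for s in (inp.smiles, out.smiles)]
        tokenizer = Tokenizer.from_corpus(corpus, config.max_length)
        model = GeneratorModel(
            kind=kind, tokenizer=tokenizer,
            params=nn.init_params(len(tokenizer), config.embedding_dim,
                                  config.latent_dim, rng),
            latent_dim=config.latent_dim, embedding_dim=config.embedding_dim,
        )

    enc, dec_in, dec_tgt = _prepare_pairs(model.tokenizer, pairs)
    n = len(enc)
    order = rng.permutation(n)
    n_train = max(1, int(round(config.split_ratio * n)))
    train_idx, val_idx = order[:n_train], order[n_train:]

    n_epochs = epochs if epochs is not None else config.epochs_for(model.kind, stage)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    tok = model.tokenizer
    for epoch in range(n_epochs):
        perm = rng.permutation(len(train_idx))
        losses = []
        for start in range(0, len(train_idx), config.batch_size):
            idx = train_idx[perm[start:start + config.batch_size]]
            e_ids, e_mask = _encode_batch(tok, [enc[i] for i in idx])
            d_in, d_mask = _encode_batch(tok, [dec_in[i] for i in idx])
            d_tgt, _ = _encode_batch(tok, [dec_tgt[i] for i in idx])
            loss, grads = nn.seq2seq_loss_and_grads(
                model.params, e_ids, e_mask, d_in, d_tgt, d_mask)
            nn.clip_gradients(grads, config.clip_norm)
            opt.step(model.params, grads)
            losses.append(loss)
        val_loss = (_batch_loss(model, enc, dec_in, dec_tgt, val_idx)
                    if len(val_idx) else float("nan"))
        model.training_log.append({
            "stage": stage, "epoch": epoch,
            "train_loss": float(np.mean(losses)), "val_loss": val_loss,
        })
    return model


def _sequence_logprobs(model: GeneratorModel, input_smiles: str,
                       output_smiles: list[str]) -> np.ndarray:
    """Mean per-token log-probability of each output given the input."""
    tok = model.tokenizer
    e = tok.encode(input_smiles)
    outs = [tok.encode(s) for s in output_smiles]
    e_ids, e_mask = _encode_batch(tok, [e] * len(outs))
    d_in, d_mask = _encode_batch(tok, [[tok.bos_id] + o for o in outs])
    d_tgt, _ = _encode_batch(tok, [o + [tok.eos_id] for o in outs])
    logp, _, _, _ = nn.seq2seq_forward(model.params, e_ids, e_mask, d_in, d_mask)
    B, S = d_tgt.shape
    rows = np.arange(B)[:, None]
    cols = np.arange(S)[None, :]
    per_tok = logp[rows, cols, d_tgt] * d_mask
    return per_tok.sum(axis=1) / np.maximum(d_mask.sum(axis=1), 1.0)


def novelty_score(model: GeneratorModel, input_fragment: Fragment,
                  output_fragment: Fragment) -> float:
    """s = 1 - exp(mean per-token log-prob), clipped to [0, 1]."""
    return novelty_scores(model, input_fragment, [output_fragment.smiles])[0]


def novelty_scores(model: GeneratorModel, input_fragment: Fragment,
                   output_smiles: list[str]) -> list[float]:
    mean_lp = _sequence_logprobs(model, input_fragment.smiles, output_smiles)
    return [float(min(1.0, max(0.0, 1.0 - np.exp(lp)))) for lp in mean_lp]


def greedy_decode(model: GeneratorModel, input_fragment: Fragment) -> str:
    """Argmax decoding; the single highest-likelihood beam-1 output."""
    tok = model.tokenizer
    e_ids, e_mask = _encode_batch(tok, [tok.encode(input_fragment.smiles)])
    h, c = nn.encoder_state(model.params, e_ids, e_mask)
    token = np.array([tok.bos_id])
    out: list[int] = []
    for _ in range(tok.max_length):
        logits, h, c = nn.decode_step(model.params, token, h, c)
        nxt = int(logits[0].argmax())
        if nxt == tok.eos_id:
            break
        out.append(nxt)
        token = np.array([nxt])
    return tok.decode(out)


def sample(
    model: GeneratorModel,
    input_fragment: Fragment,
    n: int,
    temperature: float,
    seed: int,
    batch_size: int = 256,
) -> SampleResult:
    """Sample up to *n* unique, valid, role-conformant fragments.

    Emissions that fail to parse or violate the role's attachment grammar
    are discarded and counted, as are canonical-SMILES duplicates. The
    sampling order is fully determined by ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    tok = model.tokenizer
    role = KIND_ROLE[model.kind]
    rng = np.random.default_rng(seed)
    e = tok.encode(input_fragment.smiles)

    raw: list[str] = []
    remaining = n
    while remaining > 0:
        B = min(batch_size, remaining)
        e_ids, e_mask = _encode_batch(tok, [e] * B)
        h, c = nn.encoder_state(model.params, e_ids, e_mask)
        tokens = np.full(B, tok.bos_id)
        done = np.zeros(B, dtype=bool)
        seqs: list[list[int]] = [[] for _ in range(B)]
        for _ in range(tok.max_length):
            logits, h, c = nn.decode_step(model.params, tokens, h, c)
            scaled = logits / temperature
            scaled -= scaled.max(axis=1, keepdims=True)
            probs = np.exp(scaled)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(B)
            nxt = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            nxt = np.minimum(nxt, probs.shape[1] - 1)
            for r in range(B):
                if not done[r]:
                    if nxt[r] == tok.eos_id:
                        done[r] = True
                    else:
                        seqs[r].append(int(nxt[r]))
            tokens = np.where(done, tok.pad_id, nxt)
            if done.all():
                break
        raw.extend(tok.decode(s) for s in seqs)
        remaining -= B

    n_unparseable = 0
    n_role_invalid = 0
    n_duplicate = 0
    unique: dict[str, tuple[Fragment, str]] = {}  # canonical -> (fragment, raw emission)
    for s in raw:
        try:
            frag = Fragment.from_smiles(s, role)
        except InvalidStructureError:
            n_unparseable += 1
            continue
        except AttachmentGrammarError:
            n_role_invalid += 1
            continue
        if frag.smiles in unique:
            n_duplicate += 1
            continue
        unique[frag.smiles] = (frag, s)
    # score the raw emissions (the sequences the model actually produced);
    # canonical rewrites may contain tokens outside the vocabulary
    raw_list = [rawsmi for _, rawsmi in unique.values()]
    scores = novelty_scores(model, input_fragment, raw_list) if raw_list else []
    fragments = [
        GeneratedFragment(fragment=frag, score=score, source_input=input_fragment)
        for (frag, _), score in zip(unique.values(), scores)
    ]
    return SampleResult(fragments=fragments, n_requested=n,
                        n_unparseable=n_unparseable,
                        n_role_invalid=n_role_invalid, n_duplicate=n_duplicate)
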