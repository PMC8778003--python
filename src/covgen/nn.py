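"""Minimal NumPy LSTM encoder-decoder with backpropagation through time.

Sized for desk-scale corpora (hundreds to low thousands of short token
sequences): single-layer LSTM encoder and decoder, teacher forcing, masked
cross-entropy, Adam, global-norm gradient clipping. All randomness flows
through an explicit ``numpy.random.Generator`` so runs are reproducible on
a single device.
"""

from __future__ import annotations

import numpy as np


def init_params(vocab_size: int, embedding_dim: int, hidden_dim: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform(-0.08, 0.08) init; forget-gate bias starts at +1."""
    def u(*shape):
        return rng.uniform(-0.08, 0.08, size=shape)

    params = {
        "E_enc": u(vocab_size, embedding_dim),
        "E_dec": u(vocab_size, embedding_dim),
        "Wx_enc": u(embedding_dim, 4 * hidden_dim),
        "Wh_enc": u(hidden_dim, 4 * hidden_dim),
        "b_enc": np.zeros(4 * hidden_dim),
        "Wx_dec": u(embedding_dim, 4 * hidden_dim),
        "Wh_dec": u(hidden_dim, 4 * hidden_dim),
        "b_dec": np.zeros(4 * hidden_dim),
        "W_out": u(hidden_dim, vocab_size),
        "b_out": np.zeros(vocab_size),
    }
    H = hidden_dim
    params["b_enc"][H:2 * H] = 1.0  # forget gate
    params["b_dec"][H:2 * H] = 1.0
    return params


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def lstm_step(x, h, c, Wx, Wh, b):
    """One LSTM cell step. Returns new state and the cache for backprop."""
    H = h.shape[1]
    z = x @ Wx + h @ Wh + b
    i = _sigmoid(z[:, :H])
    f = _sigmoid(z[:, H:2 * H])
    g = np.tanh(z[:, 2 * H:3 * H])
    o = _sigmoid(z[:, 3 * H:])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    cache = (x, h, c, i, f, g, o, c_new)
    return h_new, c_new, cache


def _lstm_step_backward(dh_new, dc_new, cache, Wx, Wh):
    x, h_prev, c_prev, i, f, g, o, c_new = cache
    tanh_c = np.tanh(c_new)
    do = dh_new * tanh_c
    dc_total = dc_new + dh_new * o * (1.0 - tanh_c ** 2)
    di = dc_total * g
    df = dc_total * c_prev
    dg = dc_total * i
    dz = np.concatenate(
        [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
        axis=1,
    )
    dx = dz @ Wx.T
    dh_prev = dz @ Wh.T
    dc_prev = dc_total * f
    dWx = x.T @ dz
    dWh = h_prev.T @ dz
    db = dz.sum(axis=0)
    return dx, dh_prev, dc_prev, dWx, dWh, db


def lstm_forward(X, mask, Wx, Wh, b, h0, c0):
    """Run an LSTM over (B, T, E) inputs with (B, T) masking.

    Masked positions pass the state through unchanged, so the final state
    is each row's state at its last real token.
    """
    B, T, _ = X.shape
    H = h0.shape[1]
    h, c = h0, c0
    hs = np.empty((B, T, H))
    caches = []
    for t in range(T):
        m = mask[:, t:t + 1]
        h_new, c_new, cache = lstm_step(X[:, t], h, c, Wx, Wh, b)
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
        hs[:, t] = h
        caches.append((cache, m))
    return hs, h, c, caches


def lstm_backward(dhs, dhT, dcT, caches, Wx, Wh):
    """BPTT matching :func:`lstm_forward`. ``dhs`` may be None (encoder)."""
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dX = np.empty((len(caches),) + caches[0][0][0].shape)  # (T, B, E)
    dh_carry, dc_carry = dhT, dcT
    for t in reversed(range(len(caches))):
        cache, m = caches[t]
        dh_t = dh_carry + (dhs[:, t] if dhs is not None else 0.0)
        dc_t = dc_carry
        dx, dh_prev, dc_prev, dWx_t, dWh_t, db_t = _lstm_step_backward(
            m * dh_t, m * dc_t, cache, Wx, Wh)
        dX[t] = dx
        dh_carry = (1 - m) * dh_t + dh_prev
        dc_carry = (1 - m) * dc_t + dc_prev
        dWx += dWx_t
        dWh += dWh_t
        db += db_t
    return np.transpose(dX, (1, 0, 2)), dh_carry, dc_carry, dWx, dWh, db


def log_softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def seq2seq_forward(params, enc_ids, enc_mask, dec_in, dec_mask):
    """Teacher-forced forward pass; returns log-probs and caches."""
    H = params["Wh_enc"].shape[0]
    B = enc_ids.shape[0]
    X_enc = params["E_enc"][enc_ids]
    h0 = np.zeros((B, H))
    _, hT, cT, enc_caches = lstm_forward(
        X_enc, enc_mask, params["Wx_enc"], params["Wh_enc"], params["b_enc"], h0, h0)
    X_dec = params["E_dec"][dec_in]
    hs, _, _, dec_caches = lstm_forward(
        X_dec, dec_mask, params["Wx_dec"], params["Wh_dec"], params["b_dec"], hT, cT)
    logits = hs @ params["W_out"] + params["b_out"]
    logp = log_softmax(logits)
    return logp, hs, enc_caches, dec_caches


def seq2seq_loss_and_grads(params, enc_ids, enc_mask, dec_in, dec_target, dec_mask):
    """Masked mean cross-entropy and full parameter gradients."""
    logp, hs, enc_caches, dec_caches = seq2seq_forward(
        params, enc_ids, enc_mask, dec_in, dec_mask)
    B, S, V = logp.shape
    n_tok = max(dec_mask.sum(), 1.0)
    rows = np.arange(B)[:, None]
    cols = np.arange(S)[None, :]
    loss = -(logp[rows, cols, dec_target] * dec_mask).sum() / n_tok

    dlogits = np.exp(logp)
    dlogits[rows, cols, dec_target] -= 1.0
    dlogits *= (dec_mask / n_tok)[:, :, None]

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["W_out"] = np.einsum("bsh,bsv->hv", hs, dlogits)
    grads["b_out"] = dlogits.sum(axis=(0, 1))
    dhs = dlogits @ params["W_out"].T

    H = params["Wh_enc"].shape[0]
    zeros = np.zeros((B, H))
    dX_dec, dh0_dec, dc0_dec, dWx, dWh, db = lstm_backward(
        dhs, zeros, zeros, dec_caches, params["Wx_dec"], params["Wh_dec"])
    grads["Wx_dec"], grads["Wh_dec"], grads["b_dec"] = dWx, dWh, db
    np.add.at(grads["E_dec"], dec_in, dX_dec)

    dX_enc, _, _, dWx, dWh, db = lstm_backward(
        None, dh0_dec, dc0_dec, enc_caches, params["Wx_enc"], params["Wh_enc"])
    grads["Wx_enc"], grads["Wh_enc"], grads["b_enc"] = dWx, dWh, db
    np.add.at(grads["E_enc"], enc_ids, dX_enc)
    return loss, grads


def clip_gradients(grads, max_norm: float):
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return grads


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def encoder_state(params, enc_ids, enc_mask):
    """Final encoder (h, c) for a batch of inputs."""
    H = params["Wh_enc"].shape[0]
    B = enc_ids.shape[0]
    X = params["E_enc"][enc_ids]
    h0 = np.zeros((B, H))
    _, hT, cT, _ = lstm_forward(
        X, enc_mask, params["Wx_enc"], params["Wh_enc"], params["b_enc"], h0, h0)
    return hT, cT


def decode_step(params, token_ids, h, c):
    """One decoder step for a batch of current tokens; returns logits."""
    x = params["E_dec"][token_ids]
    h, c, _ = lstm_step(x, h, c, params["Wx_dec"], params["Wh_dec"], params["b_dec"])
    logits = h @ params["W_out"] + params["b_out"]
    return logits, h, c
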