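"""BiLSTM-CRF and BiLSTM-Highway-CRF taggers in plain numpy.

Pipeline per character: embedding x -> BiLSTM -> affine projection back
to the embedding dimension -> highway combination with x (highway
variant only) -> affine projection to tag scores -> linear-chain CRF.

The highway layer computes ``y = H * T + x * (1 - T)`` where
``H = tanh(W_H u + b_H)`` transforms the projected BiLSTM path ``u`` and
the transfer gate ``T = sigmoid(W_T x + b_T)`` is driven by the original
character vector, so the gate arbitrates between trained contextual
features and the raw embedding.  The carry gate is ``1 - T`` and has no
independent parameters.

All gradients are derived by hand and verified against finite
differences in the test suite; training is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..corpus_io import TagSet
from .base import TaggedCorpus
from .crf import augment_transitions, crf_nll_and_grads, viterbi_decode
from .embeddings import UNK, EmbeddingTable

__all__ = [
    "HighwayParams",
    "highway_forward",
    "NeuralTagger",
    "train_neural",
    "DEFAULT_HYPERPARAMETERS",
]

DEFAULT_HYPERPARAMETERS = {
    "embedding_dim": 100,
    "hidden_dim": 128,        # per direction
    "dropout": 0.5,           # on the BiLSTM output before projection
    "learning_rate": 1e-3,
    "batch_size": 16,
    "epochs": 30,
    "transfer_gate_bias": -1.0,  # carry-biased start
    "grad_clip": 5.0,
}


@dataclass
class HighwayParams:
    """Weights of one highway layer (carry gate is defined as 1 - T)."""

    W_H: np.ndarray
    b_H: np.ndarray
    W_T: np.ndarray
    b_T: np.ndarray


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def highway_forward(x: np.ndarray, params: HighwayParams) -> np.ndarray:
    """Gated combination ``y = H(W_H,x)*T(W_T,x) + x*(1 - T(W_T,x))``.

    ``H`` is a tanh affine map and ``T`` a sigmoid affine map of the
    input; all products are elementwise, so output, input and both gate
    activations share one dimension.
    """
    x = np.asarray(x, dtype=float)
    d = x.shape[-1]
    for name, W in (("W_H", params.W_H), ("W_T", params.W_T)):
        if W.shape != (d, d):
            raise ValueError(f"{name} must be ({d}, {d}), got {W.shape}")
    H = np.tanh(x @ params.W_H + params.b_H)
    T = _sigmoid(x @ params.W_T + params.b_T)
    return H * T + x * (1.0 - T)


# --------------------------------------------------------------------------
# LSTM cell (gate order i, f, o, g; forget bias starts at 1)

def _lstm_forward(X, Wx, Wh, b):
    L = X.shape[0]
    h_dim = Wh.shape[0]
    hs = np.zeros((L, h_dim))
    cache = []
    h = np.zeros(h_dim)
    c = np.zeros(h_dim)
    for t in range(L):
        z = X[t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:h_dim])
        f = _sigmoid(z[h_dim : 2 * h_dim])
        o = _sigmoid(z[2 * h_dim : 3 * h_dim])
        g = np.tanh(z[3 * h_dim :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache.append((X[t], h, c, i, f, o, g, tanh_c))
        h, c = h_new, c_new
        hs[t] = h
    return hs, cache


def _lstm_backward(dhs, cache, Wx, Wh):
    L = len(cache)
    h_dim = Wh.shape[0]
    dX = np.zeros((L, Wx.shape[0]))
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * h_dim)
    dh_next = np.zeros(h_dim)
    dc_next = np.zeros(h_dim)
    for t in range(L - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, o, g, tanh_c = cache[t]
        dh = dhs[t] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            do * o * (1.0 - o),
            dg * (1.0 - g ** 2),
        ])
        dX[t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
        dWx += np.outer(x_t, dz)
        dWh += np.outer(h_prev, dz)
        db += dz
    return dX, dWx, dWh, db


class NeuralTagger:
    """A trained BiLSTM(-Highway)-CRF model."""

    def __init__(self, architecture: str, tagset: TagSet,
                 vocab: dict[str, int], params: dict[str, np.ndarray],
                 hyperparameters: dict):
        if architecture not in ("bilstm_crf", "bilstm_highway_crf"):
            raise ValueError(f"unknown architecture {architecture!r}")
        self.architecture = architecture
        self.tagset = tagset
        self.vocab = vocab
        self.params = params
        self.hyperparameters = hyperparameters
        self.loss_history: list[float] = []

    # -- forward ---------------------------------------------------------

    def _indices(self, text: str) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(c, unk) for c in text], dtype=int)

    def _forward(self, idx: np.ndarray, dropout_mask=None):
        p = self.params
        X = p["E"][idx]
        hs_f, cache_f = _lstm_forward(X, p["Wx_f"], p["Wh_f"], p["b_f"])
        hs_b, cache_b = _lstm_forward(X[::-1], p["Wx_b"], p["Wh_b"], p["b_b"])
        Hcat = np.concatenate([hs_f, hs_b[::-1]], axis=1)
        if dropout_mask is not None:
            Hcat = Hcat * dropout_mask
        cache = {"idx": idx, "X": X, "cache_f": cache_f, "cache_b": cache_b,
                 "Hcat": Hcat, "mask": dropout_mask}
        if self.architecture == "bilstm_crf":
            em = Hcat @ p["Wo"] + p["bo"]
        else:
            U = Hcat @ p["Wp"] + p["bp"]
            Hh = np.tanh(U @ p["W_H"] + p["b_H"])
            T = _sigmoid(X @ p["W_T"] + p["b_T"])
            Y = Hh * T + X * (1.0 - T)
            em = Y @ p["Wo"] + p["bo"]
            cache.update({"U": U, "Hh": Hh, "T": T, "Y": Y})
        cache["em"] = em
        return em, cache

    def _backward(self, d_em: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items() if k != "trans"}
        Hcat, X, idx = cache["Hcat"], cache["X"], cache["idx"]
        if self.architecture == "bilstm_crf":
            g["Wo"] = Hcat.T @ d_em
            g["bo"] = d_em.sum(axis=0)
            dHcat = d_em @ p["Wo"].T
            dX = np.zeros_like(X)
        else:
            Y, Hh, T, U = cache["Y"], cache["Hh"], cache["T"], cache["U"]
            g["Wo"] = Y.T @ d_em
            g["bo"] = d_em.sum(axis=0)
            dY = d_em @ p["Wo"].T
            dHh = dY * T
            dT = dY * (Hh - X)
            dX = dY * (1.0 - T)
            dZH = dHh * (1.0 - Hh ** 2)
            g["W_H"] = U.T @ dZH
            g["b_H"] = dZH.sum(axis=0)
            dU = dZH @ p["W_H"].T
            dZT = dT * T * (1.0 - T)
            g["W_T"] = X.T @ dZT
            g["b_T"] = dZT.sum(axis=0)
            dX += dZT @ p["W_T"].T
            g["Wp"] = Hcat.T @ dU
            g["bp"] = dU.sum(axis=0)
            dHcat = dU @ p["Wp"].T
        if cache["mask"] is not None:
            dHcat = dHcat * cache["mask"]
        h = p["Wh_f"].shape[0]
        dXf, g["Wx_f"], g["Wh_f"], g["b_f"] = _lstm_backward(
            dHcat[:, :h], cache["cache_f"], p["Wx_f"], p["Wh_f"])
        dXb_rev, g["Wx_b"], g["Wh_b"], g["b_b"] = _lstm_backward(
            dHcat[::-1, h:], cache["cache_b"], p["Wx_b"], p["Wh_b"])
        dX += dXf + dXb_rev[::-1]
        np.add.at(g["E"], idx, dX)
        return g

    def sequence_loss(self, text: str, tags: list[str]) -> float:
        idx = self._indices(text)
        em, _ = self._forward(idx)
        tag_idx = np.array([self.tagset.index[t] for t in tags], dtype=int)
        nll, _, _ = crf_nll_and_grads(em, self.params["trans"], tag_idx)
        return nll

    def predict_tags(self, text: str) -> list[str]:
        if not text:
            return []
        em, _ = self._forward(self._indices(text))
        path = viterbi_decode(em, self.params["trans"])
        return [self.tagset.tags[t] for t in path]


def _init_params(arch: str, vocab_size: int, d: int, h: int, K: int,
                 rng: np.random.Generator, gate_bias: float,
                 embedding_vectors: np.ndarray | None) -> dict[str, np.ndarray]:
    def glorot(m, n):
        s = np.sqrt(6.0 / (m + n))
        return rng.uniform(-s, s, size=(m, n))

    p: dict[str, np.ndarray] = {}
    if embedding_vectors is not None:
        p["E"] = embedding_vectors.astype(float).copy()
    else:
        p["E"] = rng.normal(0.0, 0.1, size=(vocab_size, d))
    for suffix in ("f", "b"):
        p[f"Wx_{suffix}"] = glorot(d, 4 * h)
        p[f"Wh_{suffix}"] = glorot(h, 4 * h)
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        p[f"b_{suffix}"] = b
    if arch == "bilstm_crf":
        p["Wo"] = glorot(2 * h, K)
        p["bo"] = np.zeros(K)
    else:
        p["Wp"] = glorot(2 * h, d)
        p["bp"] = np.zeros(d)
        p["W_H"] = glorot(d, d)
        p["b_H"] = np.zeros(d)
        p["W_T"] = glorot(d, d)
        p["b_T"] = np.full(d, gate_bias)
        p["Wo"] = glorot(d, K)
        p["bo"] = np.zeros(K)
    p["trans"] = augment_transitions(K)
    p["trans"][:K, :K] = 0.0
    p["trans"][K, :K] = 0.0
    p["trans"][:K, K + 1] = 0.0
    return p


def train_neural(
    architecture: str,
    corpus: TaggedCorpus,
    hyperparameters: dict | None = None,
    seed: int = 0,
    embeddings: EmbeddingTable | None = None,
    tagset: TagSet | None = None,
) -> NeuralTagger:
    """Train a BiLSTM-CRF or BiLSTM-Highway-CRF tagger with Adam.

    Character vectors initialize from ``embeddings`` when given (their
    dimension overrides ``embedding_dim``), else randomly.  The per-epoch
    mean NLL is recorded in ``model.loss_history``.
    """
    if architecture not in ("bilstm_crf", "bilstm_highway_crf"):
        raise ValueError(f"unknown architecture {architecture!r}")
    if not corpus:
        raise ValueError("empty training corpus")
    hp = dict(DEFAULT_HYPERPARAMETERS)
    hp.update(hyperparameters or {})
    hp["seed"] = seed
    tagset = tagset or TagSet()
    K = len(tagset)
    rng = np.random.default_rng(seed)

    if embeddings is not None:
        vocab = dict(embeddings.vocabulary)
        vectors = embeddings.vectors
        hp["embedding_dim"] = embeddings.dimension
    else:
        vocab = {}
        for text, _ in corpus:
            for ch in text:
                vocab.setdefault(ch, len(vocab))
        vocab[UNK] = len(vocab)
        vectors = None
    d, h = hp["embedding_dim"], hp["hidden_dim"]
    params = _init_params(architecture, len(vocab), d, h, K, rng,
                          hp["transfer_gate_bias"], vectors)
    model = NeuralTagger(architecture, tagset, vocab, params, hp)

    seqs = [
        (model._indices(text),
         np.array([tagset.index[t] for t in tags], dtype=int))
        for text, tags in corpus
    ]

    trainable = list(params.keys())
    m_state = {k: np.zeros_like(params[k]) for k in trainable}
    v_state = {k: np.zeros_like(params[k]) for k in trainable}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr, clip, p_drop = hp["learning_rate"], hp["grad_clip"], hp["dropout"]
    step = 0
    for epoch in range(hp["epochs"]):
        order = rng.permutation(len(seqs))
        epoch_loss = 0.0
        for batch_lo in range(0, len(order), hp["batch_size"]):
            batch = order[batch_lo : batch_lo + hp["batch_size"]]
            grads = {k: np.zeros_like(params[k]) for k in trainable}
            for j in batch:
                idx, tag_idx = seqs[j]
                mask = None
                if p_drop > 0:
                    mask = (rng.random((len(idx), 2 * h)) >= p_drop) / (1.0 - p_drop)
                em, cache = model._forward(idx, dropout_mask=mask)
                nll, d_em, d_tr = crf_nll_and_grads(em, params["trans"], tag_idx)
                epoch_loss += nll
                g = model._backward(d_em, cache)
                g["trans"] = d_tr
                for k in trainable:
                    grads[k] += g[k]
            step += 1
            for k in trainable:
                gk = grads[k] / len(batch)
                norm = np.linalg.norm(gk)
                if clip and norm > clip:
                    gk = gk * (clip / norm)
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * gk
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * gk ** 2
                m_hat = m_state[k] / (1 - beta1 ** step)
                v_hat = v_state[k] / (1 - beta2 ** step)
                params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)
        model.loss_history.append(epoch_loss / len(seqs))
    return model
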