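"""Character embeddings: skip-gram with negative sampling, in numpy.

Report text is tagged per character, so the distributed representations
are character vectors.  Training is single-threaded and fully driven by
one seed, making runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EmbeddingTable", "train_char_embeddings", "cosine"]

UNK = "<unk>"


class EmbeddingTable:
    """Character -> index vocabulary (with an unknown entry) plus vectors."""

    def __init__(self, vocabulary: dict[str, int], vectors: np.ndarray):
        if UNK not in vocabulary:
            raise ValueError(f"vocabulary must contain the {UNK!r} entry")
        if vectors.shape[0] != len(vocabulary):
            raise ValueError("one vector per vocabulary entry required")
        self.vocabulary = vocabulary
        self.vectors = vectors

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def index(self, ch: str) -> int:
        return self.vocabulary.get(ch, self.vocabulary[UNK])

    def __getitem__(self, ch: str) -> np.ndarray:
        return self.vectors[self.index(ch)]

    def indices(self, text: str) -> np.ndarray:
        return np.array([self.index(c) for c in text], dtype=int)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def train_char_embeddings(
    texts: list[str],
    d: int = 100,
    window: int = 2,
    epochs: int = 3,
    seed: int = 0,
    negative: int = 5,
    lr: float = 0.05,
) -> EmbeddingTable:
    """Skip-gram with negative sampling over character contexts.

    Every character observed in ``texts`` receives a vector; the
    unknown-character entry is the mean of all learned vectors.
    """
    texts = [t for t in texts if t]
    if not texts:
        raise ValueError("empty corpus")
    vocab: dict[str, int] = {}
    for t in texts:
        for ch in t:
            vocab.setdefault(ch, len(vocab))
    V = len(vocab)
    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    counts = np.zeros(V)
    for t in texts:
        for ch in t:
            counts[vocab[ch]] += 1
    noise = counts ** 0.75
    noise /= noise.sum()

    seqs = [np.array([vocab[c] for c in t], dtype=int) for t in texts]
    for epoch in range(epochs):
        alpha = lr * (1.0 - epoch / max(epochs, 1))
        for seq in seqs:
            L = len(seq)
            for pos in range(L):
                center = seq[pos]
                w = int(rng.integers(1, window + 1))
                lo, hi = max(0, pos - w), min(L, pos + w + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    ctx = seq[ctx_pos]
                    negs = rng.choice(V, size=negative, p=noise)
                    targets = np.concatenate(([ctx], negs))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    vecs = W_out[targets]              # (1+neg, d)
                    scores = vecs @ W_in[center]
                    sig = 1.0 / (1.0 + np.exp(-scores))
                    g = (labels - sig) * alpha          # (1+neg,)
                    grad_in = g @ vecs
                    W_out[targets] += np.outer(g, W_in[center])
                    W_in[center] += grad_in

    vocab_full = dict(vocab)
    vocab_full[UNK] = V
    vectors = np.vstack([W_in, W_in.mean(axis=0, keepdims=True)])
    return EmbeddingTable(vocab_full, vectors)
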