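"""Classical feature-based linear-chain CRF baseline.

Features per character position: unigrams in a +-2 window and the two
adjacent bigrams, crossed with the current tag, plus tag-transition
weights.  Training maximizes the L2-regularized conditional
log-likelihood with L-BFGS; gradients come from the forward-backward
expected counts in :mod:`mammokg.ner.crf`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from ..corpus_io import TagSet
from .base import TaggedCorpus
from .crf import augment_transitions, crf_nll_and_grads, viterbi_decode

__all__ = ["LinearCrfTagger", "train_crf", "extract_features"]

_BOS = "\x01"  # sentinel boundary characters, never present in reports
_EOS = "\x02"


def extract_features(text: str) -> list[list[str]]:
    """String feature keys per position (7 templates)."""
    padded = _BOS * 2 + text + _EOS * 2
    out = []
    for i in range(len(text)):
        c = padded[i + 2]
        feats = [
            f"U-2={padded[i]}",
            f"U-1={padded[i + 1]}",
            f"U0={c}",
            f"U+1={padded[i + 3]}",
            f"U+2={padded[i + 4]}",
            f"B-1={padded[i + 1]}{c}",
            f"B0={c}{padded[i + 3]}",
        ]
        out.append(feats)
    return out


class LinearCrfTagger:
    architecture = "crf"

    def __init__(self, tagset: TagSet, feature_index: dict[str, int],
                 weights: np.ndarray, transitions: np.ndarray,
                 hyperparameters: dict):
        self.tagset = tagset
        self.feature_index = feature_index
        self.weights = weights          # (F, K)
        self.transitions = transitions  # (K+2, K+2)
        self.hyperparameters = hyperparameters

    def _emissions(self, text: str) -> np.ndarray:
        K = len(self.tagset)
        em = np.zeros((len(text), K))
        for i, feats in enumerate(extract_features(text)):
            for f in feats:
                j = self.feature_index.get(f)
                if j is not None:
                    em[i] += self.weights[j]
        return em

    def predict_tags(self, text: str) -> list[str]:
        if not text:
            return []
        path = viterbi_decode(self._emissions(text), self.transitions)
        return [self.tagset.tags[t] for t in path]


def _objective(theta, seqs, F, K, l2):
    W = theta[: F * K].reshape(F, K)
    inner = theta[F * K : F * K + K * K].reshape(K, K)
    start = theta[F * K + K * K : F * K + K * K + K]
    stop = theta[F * K + K * K + K :]
    trans = augment_transitions(K)
    trans[:K, :K] = inner
    trans[K, :K] = start
    trans[:K, K + 1] = stop

    total = 0.0
    gW = np.zeros_like(W)
    g_inner = np.zeros_like(inner)
    g_start = np.zeros_like(start)
    g_stop = np.zeros_like(stop)
    for feat_mat, tags in seqs:
        em = W[feat_mat].sum(axis=1)  # (L, 7, K) -> (L, K)
        nll, d_em, d_tr = crf_nll_and_grads(em, trans, tags)
        total += nll
        np.add.at(gW, feat_mat.ravel(),
                  np.repeat(d_em, feat_mat.shape[1], axis=0))
        g_inner += d_tr[:K, :K]
        g_start += d_tr[K, :K]
        g_stop += d_tr[:K, K + 1]

    total += 0.5 * l2 * float(theta @ theta)
    grad = np.concatenate(
        [gW.ravel(), g_inner.ravel(), g_start, g_stop]
    ) + l2 * theta
    return total, grad


def train_crf(
    corpus: TaggedCorpus,
    l2: float = 0.1,
    max_iter: int = 100,
    seed: int = 0,
    tagset: TagSet | None = None,
) -> LinearCrfTagger:
    """Fit the feature CRF by L-BFGS on the regularized NLL.

    The objective is convex, so the seed only fixes bookkeeping order;
    optimization starts from zero weights.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    tagset = tagset or TagSet()
    K = len(tagset)

    feature_index: dict[str, int] = {}
    seqs = []
    for text, tags in corpus:
        feats = extract_features(text)
        for row in feats:
            for f in row:
                feature_index.setdefault(f, len(feature_index))
        feat_mat = np.array([[feature_index[f] for f in row] for row in feats],
                            dtype=int)
        tag_idx = np.array([tagset.index[t] for t in tags], dtype=int)
        seqs.append((feat_mat, tag_idx))
    F = len(feature_index)

    theta0 = np.zeros(F * K + K * K + 2 * K)
    res = minimize(
        _objective, theta0, args=(seqs, F, K, l2),
        method="L-BFGS-B", jac=True,
        options={"maxiter": max_iter, "maxls": 50},
    )
    theta = res.x
    W = theta[: F * K].reshape(F, K)
    trans = augment_transitions(K)
    trans[:K, :K] = theta[F * K : F * K + K * K].reshape(K, K)
    trans[K, :K] = theta[F * K + K * K : F * K + K * K + K]
    trans[:K, K + 1] = theta[F * K + K * K + K :]
    return LinearCrfTagger(
        tagset, feature_index, W, trans,
        hyperparameters={"l2": l2, "max_iter": max_iter, "seed": seed,
                         "converged": bool(res.success)},
    )
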