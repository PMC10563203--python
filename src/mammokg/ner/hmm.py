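"""Supervised HMM baseline: count-based MLE with add-k smoothing.

States are the 31 BIO tags, observations are characters.  Initial,
transition and emission tables are maximum-likelihood estimates from the
tagged corpus with add-k smoothing; characters never seen in training
emit a tag-independent uniform log-probability so decoding never hits a
zero-probability dead end, even at k = 0.
"""

from __future__ import annotations

import numpy as np

from ..corpus_io import TagSet
from .base import TaggedCorpus
from .crf import NEG_INF, augment_transitions, viterbi_decode

__all__ = ["HmmTagger", "train_hmm"]


class HmmTagger:
    architecture = "hmm"

    def __init__(self, tagset: TagSet, vocab: dict[str, int],
                 initial: np.ndarray, transition: np.ndarray,
                 emission: np.ndarray, hyperparameters: dict):
        self.tagset = tagset
        self.vocab = vocab
        self.initial = initial          # (K,)
        self.transition = transition    # (K, K)
        self.emission = emission        # (K, V+1), last column = unseen char
        self.hyperparameters = hyperparameters

    def predict_tags(self, text: str) -> list[str]:
        if not text:
            return []
        K = len(self.tagset)
        V = len(self.vocab)
        with np.errstate(divide="ignore"):
            log_em = np.log(self.emission)
            log_tr = np.log(self.transition)
            log_init = np.log(self.initial)
        log_em[np.isneginf(log_em)] = NEG_INF
        log_tr[np.isneginf(log_tr)] = NEG_INF
        log_init[np.isneginf(log_init)] = NEG_INF
        # unseen characters: tag-independent uniform mass
        unk = -np.log(V + 1)
        emissions = np.empty((len(text), K))
        for i, ch in enumerate(text):
            j = self.vocab.get(ch)
            emissions[i] = log_em[:, j] if j is not None else unk
        trans = augment_transitions(K)
        trans[:K, :K] = log_tr
        trans[K, :K] = log_init
        trans[:K, K + 1] = 0.0
        path = viterbi_decode(emissions, trans)
        return [self.tagset.tags[t] for t in path]


def train_hmm(corpus: TaggedCorpus, add_k: float = 0.1,
              tagset: TagSet | None = None) -> HmmTagger:
    """Estimate smoothed initial/transition/emission tables from counts."""
    if not corpus:
        raise ValueError("empty training corpus")
    tagset = tagset or TagSet()
    K = len(tagset)
    vocab: dict[str, int] = {}
    for text, _ in corpus:
        for ch in text:
            vocab.setdefault(ch, len(vocab))
    V = len(vocab)

    init = np.zeros(K)
    trans = np.zeros((K, K))
    emit = np.zeros((K, V + 1))  # final column: unseen-character pseudo-symbol
    for text, tags in corpus:
        idx = [tagset.index[t] for t in tags]
        if idx:
            init[idx[0]] += 1
        for a, b in zip(idx, idx[1:]):
            trans[a, b] += 1
        for ch, t in zip(text, idx):
            emit[t, vocab[ch]] += 1

    def normalize(counts, k):
        sm = counts + k
        totals = sm.sum(axis=-1, keepdims=True)
        out = np.divide(sm, totals, out=np.zeros_like(sm), where=totals > 0)
        return out

    return HmmTagger(
        tagset, vocab,
        initial=normalize(init[None, :], add_k)[0],
        transition=normalize(trans, add_k),
        emission=normalize(emit, add_k),
        hyperparameters={"add_k": add_k},
    )
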