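"""Linear-chain CRF core: path scores, partition function, marginals, Viterbi.

Scores live in log space.  The transition matrix is start/stop
augmented: for K tags it is (K+2) x (K+2) with START = K and STOP = K+1,
so a path ``t_1..t_L`` scores

    trans[START, t_1] + sum_i em[i, t_i] + sum_i trans[t_{i-1}, t_i]
                      + trans[t_L, STOP].

With all scores zero the partition function is ``L log K`` (the path
count), which pins down the convention.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "augment_transitions",
    "crf_log_score",
    "crf_log_partition",
    "crf_marginals",
    "crf_nll_and_grads",
    "viterbi_decode",
]

NEG_INF = -1e30  # practical -inf that survives arithmetic


def augment_transitions(K: int, fill: float = 0.0) -> np.ndarray:
    """A fresh (K+2)x(K+2) transition matrix with impossible moves blocked.

    Rows/columns K and K+1 are START and STOP; transitions into START,
    out of STOP, and START->STOP are blocked.
    """
    T = np.full((K + 2, K + 2), fill, dtype=float)
    T[:, K] = NEG_INF       # nothing enters START
    T[K + 1, :] = NEG_INF   # nothing leaves STOP
    T[K, K + 1] = NEG_INF   # empty path disallowed
    return T


def _check(emissions: np.ndarray, transitions: np.ndarray) -> tuple[int, int]:
    emissions = np.asarray(emissions)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError("emissions must be a (L >= 1, K) matrix")
    L, K = emissions.shape
    if transitions.shape != (K + 2, K + 2):
        raise ValueError(
            f"transitions must be ({K + 2}, {K + 2}) for K={K} tags, "
            f"got {transitions.shape}"
        )
    return L, K


def crf_log_score(emissions: np.ndarray, transitions: np.ndarray,
                  tags: np.ndarray) -> float:
    """Log score of one tag path (start/stop transitions included)."""
    L, K = _check(emissions, transitions)
    tags = np.asarray(tags, dtype=int)
    if tags.shape != (L,):
        raise ValueError(f"tags must have shape ({L},)")
    score = transitions[K, tags[0]] + emissions[0, tags[0]]
    for i in range(1, L):
        score += transitions[tags[i - 1], tags[i]] + emissions[i, tags[i]]
    score += transitions[tags[-1], K + 1]
    return float(score)


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """Log of the sum over all K^L tag paths of exp(path score)."""
    L, K = _check(emissions, transitions)
    alpha = transitions[K, :K] + emissions[0]
    for i in range(1, L):
        alpha = logsumexp(alpha[:, None] + transitions[:K, :K], axis=0) + emissions[i]
    return float(logsumexp(alpha + transitions[:K, K + 1]))


def crf_marginals(emissions: np.ndarray, transitions: np.ndarray):
    """Forward-backward: (logZ, unary marginals (L,K), pairwise (L-1,K,K))."""
    L, K = _check(emissions, transitions)
    inner = transitions[:K, :K]
    alpha = np.empty((L, K))
    beta = np.empty((L, K))
    alpha[0] = transitions[K, :K] + emissions[0]
    for i in range(1, L):
        alpha[i] = logsumexp(alpha[i - 1][:, None] + inner, axis=0) + emissions[i]
    beta[L - 1] = transitions[:K, K + 1]
    for i in range(L - 2, -1, -1):
        beta[i] = logsumexp(inner + (emissions[i + 1] + beta[i + 1])[None, :], axis=1)
    logZ = float(logsumexp(alpha[L - 1] + beta[L - 1]))
    unary = np.exp(alpha + beta - logZ)
    pairwise = np.empty((max(L - 1, 0), K, K))
    for i in range(L - 1):
        m = (alpha[i][:, None] + inner
             + (emissions[i + 1] + beta[i + 1])[None, :]) - logZ
        pairwise[i] = np.exp(m)
    return logZ, unary, pairwise


def crf_nll_and_grads(emissions: np.ndarray, transitions: np.ndarray,
                      tags: np.ndarray):
    """Negative log-likelihood of a gold path and its gradients.

    Returns ``(nll, d_emissions, d_transitions)`` where the gradients are
    expected feature counts minus observed ones (so gradient *descent*
    on the NLL).  The NLL is always >= 0.
    """
    L, K = _check(emissions, transitions)
    tags = np.asarray(tags, dtype=int)
    logZ, unary, pairwise = crf_marginals(emissions, transitions)
    gold = crf_log_score(emissions, transitions, tags)
    nll = logZ - gold

    d_em = unary.copy()
    d_em[np.arange(L), tags] -= 1.0

    d_tr = np.zeros_like(transitions)
    if L > 1:
        d_tr[:K, :K] = pairwise.sum(axis=0)
        for i in range(1, L):
            d_tr[tags[i - 1], tags[i]] -= 1.0
    # START->t fires iff t_1 = t, so its expected count is the first unary
    # marginal; symmetrically for t->STOP and the last position.
    d_tr[K, :K] = unary[0]
    d_tr[K, tags[0]] -= 1.0
    d_tr[:K, K + 1] += unary[-1]
    d_tr[tags[-1], K + 1] -= 1.0
    return float(nll), d_em, d_tr


def viterbi_decode(emissions: np.ndarray, transitions: np.ndarray) -> list[int]:
    """Highest-scoring tag path; ties break toward the lowest tag index."""
    L, K = _check(emissions, transitions)
    inner = transitions[:K, :K]
    delta = transitions[K, :K] + emissions[0]
    back = np.empty((L, K), dtype=int)
    for i in range(1, L):
        scores = delta[:, None] + inner  # (prev, cur)
        back[i] = np.argmax(scores, axis=0)  # first max = lowest index
        delta = scores[back[i], np.arange(K)] + emissions[i]
    delta = delta + transitions[:K, K + 1]
    path = [int(np.argmax(delta))]
    for i in range(L - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return path[::-1]
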