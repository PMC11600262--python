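"""Linear-chain CRF: forward algorithm, marginals, masked Viterbi.

The chain scores a tag sequence ``y`` over ``L`` tokens as

    score(y) = start[y_0] + sum_t emissions[t, y_t]
             + sum_t transitions[y_{t-1}, y_t] + stop[y_{L-1}]

Training normalises by the log-partition over all ``T^L`` sequences
(forward algorithm); decoding maximises the same score (Viterbi),
optionally under a hard BIO-validity mask so that the decoded sequence
is always well-formed regardless of what training learned.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from litreg.corpus import BIO_TAGS

NEG_INF = -1e30


class CrfError(ValueError):
    pass


def bio_transition_mask(tags: tuple[str, ...] = BIO_TAGS):
    """(allowed T x T matrix, allowed-start vector) for the BIO alphabet.

    ``I-X`` may only follow ``B-X`` or ``I-X``; a sequence may not
    start with ``I-X``.
    """
    T = len(tags)
    allowed = np.ones((T, T), dtype=bool)
    start_ok = np.ones(T, dtype=bool)
    for j, tj in enumerate(tags):
        if not tj.startswith("I-"):
            continue
        label = tj[2:]
        start_ok[j] = False
        for i, ti in enumerate(tags):
            if ti not in (f"B-{label}", f"I-{label}"):
                allowed[i, j] = False
    return allowed, start_ok


def _check(emissions: np.ndarray) -> None:
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise CrfError("emissions must be a non-empty L x T matrix")
    if not np.all(np.isfinite(emissions)):
        raise CrfError("non-finite emission scores")


def path_score(emissions, transitions, start, stop, y) -> float:
    s = start[y[0]] + emissions[0, y[0]]
    for t in range(1, len(y)):
        s += transitions[y[t - 1], y[t]] + emissions[t, y[t]]
    return float(s + stop[y[-1]])


def log_partition(emissions, transitions, start, stop) -> float:
    """log sum over all tag sequences of exp(path score)."""
    _check(emissions)
    alpha = start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = logsumexp(alpha[:, None] + transitions, axis=0) + emissions[t]
    return float(logsumexp(alpha + stop))


def forward_backward(emissions, transitions, start, stop):
    """Unary and pairwise posterior marginals plus logZ.

    Returns ``(unary L x T, pairwise (L-1) x T x T, logZ)`` where
    ``pairwise[t, i, j] = P(y_t = i, y_{t+1} = j | x)``.
    """
    _check(emissions)
    L, T = emissions.shape
    alpha = np.empty((L, T))
    alpha[0] = start + emissions[0]
    for t in range(1, L):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + transitions, axis=0) + emissions[t]
    beta = np.empty((L, T))
    beta[L - 1] = stop
    for t in range(L - 2, -1, -1):
        beta[t] = logsumexp(
            transitions + emissions[t + 1] + beta[t + 1], axis=1
        )
    logZ = float(logsumexp(alpha[-1] + stop))
    unary = np.exp(alpha + beta - logZ)
    pairwise = np.empty((max(L - 1, 0), T, T))
    for t in range(L - 1):
        lp = (
            alpha[t][:, None]
            + transitions
            + emissions[t + 1][None, :]
            + beta[t + 1][None, :]
            - logZ
        )
        pairwise[t] = np.exp(lp)
    return unary, pairwise, logZ


def viterbi(emissions, transitions, start, stop,
            allowed=None, start_ok=None):
    """Best-scoring tag index sequence, optionally BIO-masked.

    Raises :class:`CrfError` when every path is masked out.
    """
    _check(emissions)
    L, T = emissions.shape
    trans = transitions.copy()
    first = start + emissions[0]
    if allowed is not None:
        trans = np.where(allowed, trans, NEG_INF)
    if start_ok is not None:
        first = np.where(start_ok, first, NEG_INF)
    delta = first
    back = np.zeros((L, T), dtype=np.int64)
    for t in range(1, L):
        cand = delta[:, None] + trans
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(T)] + emissions[t]
    delta = delta + stop
    if np.max(delta) <= NEG_INF / 2:
        raise CrfError("all tag paths are masked out")
    y = np.empty(L, dtype=np.int64)
    y[L - 1] = int(np.argmax(delta))
    for t in range(L - 1, 0, -1):
        y[t - 1] = back[t, y[t]]
    return y.tolist(), float(np.max(delta))
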