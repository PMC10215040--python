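"""Exact linear-chain CRF inference in log space.

Scores live in a per-position emission matrix ``E`` (``L x T``) and a
transition matrix ``A`` of shape ``(T+2) x (T+2)`` whose last two indices
are the virtual START and STOP states. A path ``t_1..t_L`` scores

    A[START, t_1] + sum_i E[i, t_i] + sum_i A[t_i, t_{i+1}] + A[t_L, STOP]

and the model is globally normalized over all legal paths. Legality is an
optional boolean mask of the same shape as ``A``: forbidden cells behave
as score -inf. All recursions (forward partition, Viterbi max-product,
forward-backward posteriors) are log-sum-exp stabilized.

Viterbi ties break toward the lower tag index at every backtracking step,
so decoding is fully deterministic.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

NEG_INF = -np.inf


class CRFError(ValueError):
    pass


def _effective_trans(trans: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is None:
        return np.asarray(trans, dtype=np.float64)
    trans = np.asarray(trans, dtype=np.float64)
    if mask.shape != trans.shape:
        raise CRFError(f"mask shape {mask.shape} != trans shape {trans.shape}")
    out = np.where(mask, trans, NEG_INF)
    return out


def _split(trans_eff: np.ndarray):
    n_total = trans_eff.shape[0]
    T = n_total - 2
    start, stop = T, T + 1
    return T, trans_eff[start, :T], trans_eff[:T, stop], trans_eff[:T, :T]


def path_score(
    emissions: np.ndarray,
    trans: np.ndarray,
    tags: Sequence[int],
    mask: Optional[np.ndarray] = None,
) -> float:
    """Unnormalized log score of one tag path (``-inf`` if masked out)."""
    E = np.asarray(emissions, dtype=np.float64)
    A = _effective_trans(trans, mask)
    T, a_start, a_stop, a_inner = _split(A)
    tags = np.asarray(tags, dtype=np.int64)
    L = E.shape[0]
    if len(tags) != L:
        raise CRFError(f"path length {len(tags)} != sequence length {L}")
    if L == 0:
        raise CRFError("empty sequence")
    score = a_start[tags[0]] + E[np.arange(L), tags].sum() + a_stop[tags[-1]]
    if L > 1:
        score += a_inner[tags[:-1], tags[1:]].sum()
    return float(score)


def log_partition(
    emissions: np.ndarray,
    trans: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """log sum over all legal paths of exp(path score) — forward algorithm."""
    alpha = _forward(np.asarray(emissions, float), _effective_trans(trans, mask))
    T = emissions.shape[1]
    a_stop = _effective_trans(trans, mask)[:T, T + 1]
    return float(logsumexp(alpha[-1] + a_stop))


def _forward(E: np.ndarray, A: np.ndarray) -> np.ndarray:
    """alpha[i, t] = log sum of prefix paths ending in tag t at position i
    (emission at i included)."""
    T, a_start, _, a_inner = _split(A)
    L = E.shape[0]
    alpha = np.empty((L, T))
    alpha[0] = a_start + E[0]
    for i in range(1, L):
        # broadcast: prev-state axis 0, next-state axis 1
        alpha[i] = logsumexp(alpha[i - 1][:, None] + a_inner, axis=0) + E[i]
    return alpha


def _backward(E: np.ndarray, A: np.ndarray) -> np.ndarray:
    """beta[i, t] = log sum of suffix paths from tag t at position i
    (emission at i excluded, STOP transition included)."""
    T, _, a_stop, a_inner = _split(A)
    L = E.shape[0]
    beta = np.empty((L, T))
    beta[-1] = a_stop
    for i in range(L - 2, -1, -1):
        beta[i] = logsumexp(a_inner + (E[i + 1] + beta[i + 1])[None, :], axis=1)
    return beta


def nll(
    emissions: np.ndarray,
    trans: np.ndarray,
    tags: Sequence[int],
    mask: Optional[np.ndarray] = None,
) -> float:
    """Negative log-likelihood of the gold path; >= 0, exactly 0 when the
    gold path carries all probability mass."""
    return log_partition(emissions, trans, mask) - path_score(
        emissions, trans, tags, mask
    )


def marginals(
    emissions: np.ndarray,
    trans: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-position posterior tag probabilities via forward-backward.

    Rows sum to 1 (up to floating error).
    """
    E = np.asarray(emissions, dtype=np.float64)
    A = _effective_trans(trans, mask)
    alpha = _forward(E, A)
    beta = _backward(E, A)
    log_post = alpha + beta
    log_z = logsumexp(log_post[0])
    return np.exp(log_post - log_z)


def nll_gradients(
    emissions: np.ndarray,
    trans: np.ndarray,
    tags: Sequence[int],
    mask: Optional[np.ndarray] = None,
):
    """NLL and its exact gradients w.r.t. emissions and transitions.

    d/dE = posterior marginals minus the gold one-hot path;
    d/dA = expected transition counts minus gold counts (including the
    START row and STOP column). Masked-out cells get zero gradient.
    """
    E = np.asarray(emissions, dtype=np.float64)
    A = _effective_trans(trans, mask)
    tags = np.asarray(tags, dtype=np.int64)
    L, T = E.shape
    start, stop = T, T + 1
    _, _, a_stop, a_inner = _split(A)

    alpha = _forward(E, A)
    beta = _backward(E, A)
    log_z = float(logsumexp(alpha[-1] + a_stop))

    gamma = np.exp(alpha + beta - log_z)  # L x T posteriors

    d_E = gamma.copy()
    d_E[np.arange(L), tags] -= 1.0

    d_A = np.zeros_like(A)
    # START row and STOP column expectations are the boundary posteriors
    d_A[start, :T] = gamma[0]
    d_A[start, tags[0]] -= 1.0
    d_A[:T, stop] = gamma[-1]
    d_A[tags[-1], stop] -= 1.0
    for i in range(L - 1):
        with np.errstate(invalid="ignore"):
            log_xi = (
                alpha[i][:, None]
                + a_inner
                + (E[i + 1] + beta[i + 1])[None, :]
                - log_z
            )
        xi = np.exp(np.nan_to_num(log_xi, nan=NEG_INF, neginf=NEG_INF))
        d_A[:T, :T] += xi
        d_A[tags[i], tags[i + 1]] -= 1.0

    value = log_z - path_score(emissions, trans, tags, mask)
    if mask is not None:
        d_A[~mask] = 0.0
    return value, d_E, d_A


def viterbi(
    emissions: np.ndarray,
    trans: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Highest-scoring legal tag path (argmax decoding).

    Raises :class:`CRFError` when the mask admits no path at all.
    """
    E = np.asarray(emissions, dtype=np.float64)
    A = _effective_trans(trans, mask)
    T, a_start, a_stop, a_inner = _split(A)
    L = E.shape[0]
    if L == 0:
        raise CRFError("empty sequence")

    delta = a_start + E[0]
    backptr = np.zeros((L, T), dtype=np.int64)
    for i in range(1, L):
        cand = delta[:, None] + a_inner  # prev x next
        backptr[i] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[backptr[i], np.arange(T)] + E[i]
    final = delta + a_stop
    best_last = int(np.argmax(final))
    if not np.isfinite(final[best_last]):
        raise CRFError("no legal path under the transition constraints")
    path = np.empty(L, dtype=np.int64)
    path[-1] = best_last
    for i in range(L - 1, 0, -1):
        path[i - 1] = backptr[i, path[i]]
    return path
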