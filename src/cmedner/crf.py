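"""Linear-chain conditional random field.

Scores a label sequence ``y`` for an ``n``-position sentence as

    score(X, y) = sum_{i=0..n} A[y_i, y_{i+1}] + sum_{i=1..n} P[i, y_i]

where ``P`` is the per-position emission matrix, ``A`` the transition
matrix over the label set augmented with START and STOP states
(``y_0 = START``, ``y_{n+1} = STOP``), and

    P(y | X) = exp(score(X, y)) / sum_{y~} exp(score(X, y~)).

The log-partition function is computed by the forward recursion in
log-space; decoding is max-product Viterbi with backpointers.  A brute
force enumeration oracle over all ``L**n`` label sequences is provided for
testing.  Transitions into START and out of STOP are walled off with a
large negative constant rather than a true -inf so gradients stay finite.

``nll_loss`` is the differentiable training objective: it accepts batched
emissions as an autodiff :class:`~cmedner.autodiff.Tensor` and
backpropagates into both the emissions and the transition matrix.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, logsumexp, reshape, tsum

__all__ = [
    "WALL",
    "CRFParams",
    "sequence_score",
    "log_partition",
    "viterbi_decode",
    "enumerate_all",
    "nll_loss",
]

WALL = -1e4  # effectively -inf, kept finite so gradients never NaN

_ENUM_LIMIT = 10 ** 6


def _logsumexp_np(a: np.ndarray, axis=None) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True)) + m
    return np.squeeze(out, axis=axis) if axis is not None else out.reshape(())


class CRFParams:
    """Transition scores over ``L`` labels augmented with START and STOP.

    The learned matrix is ``(L+2, L+2)``; :meth:`matrix` returns the
    effective transitions with the START/STOP walls applied additively.
    Index ``L`` is START, ``L+1`` is STOP.
    """

    def __init__(self, n_labels: int, transitions=None, trainable: bool = True):
        if n_labels < 1:
            raise ValueError("need at least one label")
        self.n_labels = int(n_labels)
        self.start = self.n_labels
        self.stop = self.n_labels + 1
        full = self.n_labels + 2
        if transitions is None:
            transitions = np.zeros((full, full))
        if isinstance(transitions, Tensor):
            self.transitions = transitions
        else:
            transitions = np.asarray(transitions, dtype=np.float64)
            if transitions.shape != (full, full):
                raise ValueError(f"transitions must be {(full, full)}, got {transitions.shape}")
            self.transitions = Tensor(transitions, requires_grad=trainable)
        wall = np.zeros((full, full))
        wall[:, self.start] = WALL  # nothing transitions into START
        wall[self.stop, :] = WALL  # nothing transitions out of STOP
        self._wall = wall

    def matrix(self) -> np.ndarray:
        """Effective transition matrix (learned values + walls), as ndarray."""
        return self.transitions.data + self._wall

    def matrix_tensor(self) -> Tensor:
        """Effective transition matrix on the autodiff tape."""
        return self.transitions + self._wall

    def parameters(self) -> list[Tensor]:
        return [self.transitions] if self.transitions.requires_grad else []


def _as_emissions(P) -> np.ndarray:
    P = np.asarray(getattr(P, "data", P), dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError(f"emission matrix must be (n >= 1, L), got {P.shape}")
    return P


def _check_labels(y: Sequence[int], n: int, L: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.intp)
    if y.shape != (n,):
        raise ValueError(f"label sequence length {y.shape} != {n} positions")
    if y.size and (y.min() < 0 or y.max() >= L):
        raise ValueError(f"label index out of range [0, {L})")
    return y


def sequence_score(P, crf: CRFParams, y: Sequence[int]) -> float:
    """Exact score of one label sequence, including boundary transitions."""
    P = _as_emissions(P)
    n, L = P.shape
    if L != crf.n_labels:
        raise ValueError(f"emissions have {L} labels, CRF has {crf.n_labels}")
    y = _check_labels(y, n, L)
    A = crf.matrix()
    s = A[crf.start, y[0]] + A[y[-1], crf.stop]
    s += P[np.arange(n), y].sum()
    if n > 1:
        s += A[y[:-1], y[1:]].sum()
    return float(s)


def log_partition(P, crf: CRFParams) -> float:
    """log sum over all label sequences of exp(score), via the forward
    recursion in log-space."""
    P = _as_emissions(P)
    n, L = P.shape
    A = crf.matrix()
    alpha = A[crf.start, :L] + P[0]
    inner = A[:L, :L]
    for i in range(1, n):
        alpha = _logsumexp_np(alpha[:, None] + inner + P[i][None, :], axis=0)
    return float(_logsumexp_np(alpha + A[:L, crf.stop]))


def viterbi_decode(P, crf: CRFParams) -> tuple[list[int], float]:
    """Best label sequence and its score, by max-product dynamic programming.

    Ties are broken toward the lowest label index (NumPy argmax convention),
    so decoding is deterministic.
    """
    P = _as_emissions(P)
    n, L = P.shape
    A = crf.matrix()
    inner = A[:L, :L]
    delta = A[crf.start, :L] + P[0]
    backptr = np.empty((n - 1, L), dtype=np.intp) if n > 1 else None
    for i in range(1, n):
        cand = delta[:, None] + inner  # (prev, next)
        best_prev = np.argmax(cand, axis=0)
        backptr[i - 1] = best_prev
        delta = cand[best_prev, np.arange(L)] + P[i]
    final = delta + A[:L, crf.stop]
    last = int(np.argmax(final))
    score = float(final[last])
    path = [last]
    for i in range(n - 2, -1, -1):
        last = int(backptr[i][last])
        path.append(last)
    path.reverse()
    return path, score


def enumerate_all(P, crf: CRFParams) -> list[tuple[tuple[int, ...], float]]:
    """Every label sequence with its exact score (test oracle).

    Raises ``ValueError`` when the instance has more than 10**6 sequences.
    """
    P = _as_emissions(P)
    n, L = P.shape
    if L ** n > _ENUM_LIMIT:
        raise ValueError(f"enumeration of {L}^{n} sequences exceeds {_ENUM_LIMIT}")
    A = crf.matrix()
    pos = np.arange(n)
    out = []
    for y in itertools.product(range(L), repeat=n):
        ya = np.asarray(y, dtype=np.intp)
        s = A[crf.start, ya[0]] + A[ya[-1], crf.stop] + P[pos, ya].sum()
        if n > 1:
            s += A[ya[:-1], ya[1:]].sum()
        out.append((y, float(s)))
    return out


# ---------------------------------------------------------------------------
# differentiable loss
# ---------------------------------------------------------------------------

def nll_loss(emissions, crf: CRFParams, tags, mask=None, reduction: str = "sum") -> Tensor:
    """Negative log-likelihood of gold paths over a batch.

    ``emissions`` is ``(B, n, L)`` (a single ``(n, L)`` matrix is promoted);
    ``tags`` the gold label indices ``(B, n)``; ``mask`` marks real
    positions and must be a contiguous prefix per sequence (right padding).
    Sequences whose mask is empty contribute zero.  Differentiable with
    respect to emissions and transitions.
    """
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    E = as_tensor(emissions)
    if E.ndim == 2:
        E = reshape(E, (1,) + E.shape)
        tags = np.asarray(tags).reshape(1, -1)
        if mask is not None:
            mask = np.asarray(mask).reshape(1, -1)
    if E.ndim != 3:
        raise ValueError(f"emissions must be (B, n, L), got {E.shape}")
    B, n, L = E.shape
    if L != crf.n_labels:
        raise ValueError(f"emissions have {L} labels, CRF has {crf.n_labels}")
    if B == 0 or n == 0:
        return Tensor(0.0)
    tags = np.asarray(tags, dtype=np.intp)
    if tags.shape != (B, n):
        raise ValueError(f"tags must be {(B, n)}, got {tags.shape}")
    if mask is None:
        mask = np.ones((B, n), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (B, n):
        raise ValueError(f"mask must be {(B, n)}, got {mask.shape}")
    # Right-padding contract: each row's True positions form a prefix.
    lengths = mask.sum(axis=1)
    if not np.array_equal(mask, np.arange(n)[None, :] < lengths[:, None]):
        raise ValueError("mask must be a contiguous prefix per sequence")
    if (tags[mask] >= L).any() or (tags[mask] < 0).any():
        raise ValueError(f"tag index out of range [0, {L})")
    seq_alive = (lengths > 0).astype(np.float64)

    A = crf.matrix_tensor()
    a_start = A[crf.start, :L]  # (L,)
    a_stop = A[:L, crf.stop]  # (L,)
    inner = A[:L, :L]

    mf = mask.astype(np.float64)
    # forward recursion (log-space), frozen past each sequence's length
    alpha = reshape(a_start, (1, L)) + E[:, 0, :]
    for i in range(1, n):
        nxt = logsumexp(
            reshape(alpha, (B, L, 1)) + reshape(inner, (1, L, L)) + reshape(E[:, i, :], (B, 1, L)),
            axis=1,
        )
        mi = mf[:, i][:, None]
        alpha = nxt * mi + alpha * (1.0 - mi)
    log_z = logsumexp(alpha + reshape(a_stop, (1, L)), axis=1)  # (B,)

    # gold-path score via one-hot contractions (keeps indexing off the tape)
    onehot = np.eye(L)[tags] * mf[:, :, None]  # (B, n, L)
    em_score = tsum(E * onehot, axis=(1, 2))  # (B,)
    start_score = tsum(reshape(a_start, (1, L)) * onehot[:, 0, :], axis=1)
    last_onehot = np.zeros((B, L))
    rows = lengths > 0
    last_onehot[rows, tags[rows, lengths[rows] - 1]] = 1.0
    stop_score = tsum(reshape(a_stop, (1, L)) * last_onehot, axis=1)
    if n > 1:
        pair = onehot[:, :-1, :, None] * onehot[:, 1:, None, :]  # (B, n-1, L, L)
        trans_score = tsum(reshape(inner, (1, 1, L, L)) * pair, axis=(1, 2, 3))
        gold = em_score + start_score + stop_score + trans_score
    else:
        gold = em_score + start_score + stop_score

    nll_per_seq = (log_z + gold * -1.0) * seq_alive
    total = tsum(nll_per_seq)
    if reduction == "mean":
        denom = max(1.0, float(seq_alive.sum()))
        total = total * (1.0 / denom)
    return total
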