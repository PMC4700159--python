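"""Pairwise coupling: combine all pairwise class probabilities r_ij into one
M-class posterior vector.

Given pairwise estimates ``r_ij ~ p(y=i | y in {i,j}, x)`` with
``r_ij + r_ji = 1``, the class probabilities P = (p_1..p_M) are recovered by
minimizing

    (1/2) sum_i sum_{j != i} (r_ji p_i - r_ij p_j)^2  =  (1/2) P^T Q P

over the probability simplex, where ``Q_ii = sum_{s != i} r_si^2`` and
``Q_ij = -r_ji r_ij`` for ``i != j`` (Q is positive semidefinite).  The
primary solver is the published coordinate-descent sweep; a
Kullback-Leibler iterative-scaling solver (the Hastie-Tibshirani approach)
and plain pairwise voting are provided as baselines.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "validate_pairwise",
    "build_Q",
    "solve_coupling",
    "solve_coupling_kl",
    "vote",
    "coupling_objective",
]

#: published defaults of the coordinate-descent loop
DEFAULT_ITMAX = 100


def default_eps(M: int) -> float:
    """Published stopping threshold of the coupling iteration: 0.005/M."""
    return 0.005 / M


def validate_pairwise(r: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Validate a pairwise probability matrix: off-diagonal in (0,1) and
    ``r_ij + r_ji = 1``; the diagonal is unused."""
    r = np.asarray(r, dtype=float)
    M = r.shape[0]
    if r.shape != (M, M) or M < 2:
        raise ValueError("r must be a square matrix with M >= 2")
    off = ~np.eye(M, dtype=bool)
    if np.any(r[off] <= 0) or np.any(r[off] >= 1):
        raise ValueError("off-diagonal pairwise probabilities must lie in (0, 1)")
    if np.max(np.abs(r + r.T - 1.0)[off]) > tol:
        raise ValueError("pairwise probabilities must satisfy r_ij + r_ji = 1")
    return r


def build_Q(r: np.ndarray) -> np.ndarray:
    """Quadratic-coupling matrix: ``Q_ii = sum_{s!=i} r_si^2``,
    ``Q_ij = -r_ji r_ij`` (i != j); symmetric positive semidefinite."""
    r = validate_pairwise(r)
    M = r.shape[0]
    Q = -(r.T * r)
    np.fill_diagonal(Q, 0.0)
    r2 = r * r
    np.fill_diagonal(r2, 0.0)
    np.fill_diagonal(Q, r2.sum(axis=0))
    return Q


def coupling_objective(Q: np.ndarray, P: np.ndarray) -> float:
    """The coupled-probability objective ``(1/2) P^T Q P``."""
    return 0.5 * float(P @ Q @ P)


def solve_coupling(
    Q: np.ndarray,
    eps: float | None = None,
    itmax: int = DEFAULT_ITMAX,
) -> np.ndarray:
    """Minimize ``(1/2) P^T Q P`` on the simplex by the published
    coordinate-descent sweep.

    Starting from the uniform vector P = 1/M, each sweep visits every class
    t, takes the exact coordinate step
    ``delta = (-(QP)_t + P^T Q P) / Q_tt``, and renormalizes all entries by
    ``1 + delta``, maintaining QP and P^T Q P incrementally.  Iteration stops
    when ``max_t |(QP)_t - P^T Q P| < eps`` (default 0.005/M) or after
    ``itmax`` sweeps (default 100).
    """
    Q = np.asarray(Q, dtype=float)
    M = Q.shape[0]
    if eps is None:
        eps = default_eps(M)
    if np.any(np.diag(Q) <= 0):
        raise ValueError("Q has a zero diagonal entry; invalid pairwise matrix")
    P = np.full(M, 1.0 / M)
    QP = Q @ P
    pQp = float(P @ QP)
    for _ in range(itmax):
        if np.max(np.abs(QP - pQp)) < eps:
            break
        for t in range(M):
            delta = (-QP[t] + pQp) / Q[t, t]
            P[t] += delta
            pQp = (pQp + delta * (delta * Q[t, t] + 2.0 * QP[t])) / (1.0 + delta) ** 2
            QP = (QP + delta * Q[t, :]) / (1.0 + delta)
            P /= 1.0 + delta
    P = np.clip(P, 0.0, None)
    return P / P.sum()


def solve_coupling_kl(
    r: np.ndarray,
    n: np.ndarray | None = None,
    tol: float = 1e-6,
    itmax: int = 1000,
) -> np.ndarray:
    """Kullback-Leibler coupling baseline (Hastie-Tibshirani iterative
    scaling).

    Repeats ``p_i <- p_i * (sum_{j!=i} n_ij r_ij) / (sum_{j!=i} n_ij mu_ij)``
    with ``mu_ij = p_i / (p_i + p_j)``, renormalizing each pass, until the
    largest per-entry change is below ``tol`` or ``itmax`` passes.  Pair
    counts ``n_ij`` default to uniform (the intended use is near-balanced
    pairs).
    """
    r = validate_pairwise(r)
    M = r.shape[0]
    if n is None:
        n = np.ones((M, M))
    n = np.asarray(n, dtype=float)
    off = ~np.eye(M, dtype=bool)
    P = np.full(M, 1.0 / M)
    for _ in range(itmax):
        mu = P[:, None] / (P[:, None] + P[None, :])
        num = np.sum(np.where(off, n * r, 0.0), axis=1)
        den = np.sum(np.where(off, n * mu, 0.0), axis=1)
        P_new = P * num / den
        P_new /= P_new.sum()
        if np.max(np.abs(P_new - P)) < tol:
            P = P_new
            break
        P = P_new
    return P


def vote(r: np.ndarray) -> int:
    """Majority voting over the pairwise decisions.

    Each unordered pair (i, j) contributes one vote to its winner
    (``r_ij > 0.5`` votes for i, otherwise j; an exact pairwise tie votes for
    the lower index).  Returns the 0-based index of the class with most
    votes; overall ties break to the lowest class index.
    """
    r = validate_pairwise(r)
    M = r.shape[0]
    votes = np.zeros(M, dtype=int)
    for i in range(M):
        for j in range(i + 1, M):
            votes[i if r[i, j] >= 0.5 else j] += 1
    return int(np.argmax(votes))  # argmax takes the first (lowest) maximizer
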