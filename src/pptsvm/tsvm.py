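"""Nonlinear twin support vector machine: dual QPs, surfaces, distances,
labels, and the ranking continuous output.

A twin SVM fits two nonparallel kernel-generated surfaces

    f1(x) = K(x, C) u1 + b1 = 0,    f2(x) = K(x, C) u2 + b2 = 0,

where ``C = [A; B]`` stacks the training samples of the two classes.  Surface
1 is pulled close to class +1 samples (rows of ``A``) and pushed at least unit
distance from class -1 samples (rows of ``B``); surface 2 symmetrically.  Each
surface comes from a box-constrained convex dual QP of the size of the
*opposite* class only, which is why twin SVMs train markedly faster than a
single large-margin machine.

A test point is labeled by the nearer surface (normalized perpendicular
distance).  On top of the hard label, ``continuous_output`` produces a signed
ranking score f(x): its sign matches the label and its magnitude shrinks as
the point approaches the decision boundary, which is what the Platt sigmoid
in :mod:`pptsvm.calibration` is fitted to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import lsq_linear

from .kernel import KernelSpec, gram

__all__ = [
    "TSVMTrainingProblem",
    "TSVMBinaryModel",
    "train_tsvm",
    "solve_box_qp",
    "dual_objective",
    "perpendicular_distances",
    "predict_label",
    "continuous_output",
]

logger = logging.getLogger(__name__)

#: tie tolerance for the nearer-surface decision rule
TIE_TOL = 1e-12


@dataclass(frozen=True)
class TSVMTrainingProblem:
    """A binary TSVM training problem.

    Parameters
    ----------
    A : array (m1, n)
        Samples of class +1.
    B : array (m2, n)
        Samples of class -1.
    c1, c2 : float
        Positive penalty parameters of the two primal problems.
    kernel : KernelSpec
        Gaussian kernel specification.
    regularizer : float
        Relative Tikhonov term added to H^T H and G^T G before inversion
        (scaled by the mean diagonal), needed because these Gram-augmented
        normal matrices are singular whenever m1 + m2 + 1 exceeds their rank.
    """

    A: np.ndarray
    B: np.ndarray
    c1: float
    c2: float
    kernel: KernelSpec
    regularizer: float = 1e-7

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        if A.shape[0] < 1 or B.shape[0] < 1:
            raise ValueError("each class needs at least one sample")
        if A.shape[1] != B.shape[1]:
            raise ValueError("A and B must share the feature dimension")
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("penalty parameters c1, c2 must be positive")
        if not self.regularizer > 0:
            raise ValueError("regularizer must be positive")


@dataclass
class TSVMBinaryModel:
    """A trained binary TSVM.

    ``C`` stacks the training samples ``[A; B]``; ``(u1, b1)`` and
    ``(u2, b2)`` parameterize the class +1 and class -1 surfaces.  ``gamma``
    weights the ranking continuous output.  The dual multipliers ``alpha``
    (box ``[0, c1]``) and ``beta`` (box ``[0, c2]``) are retained for
    diagnostics.
    """

    C: np.ndarray
    u1: np.ndarray
    b1: float
    u2: np.ndarray
    b2: float
    kernel: KernelSpec
    gamma: float = 1.0
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    _Kcc: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")

    @property
    def Kcc(self) -> np.ndarray:
        """Train-time Gram matrix over C, computed once and cached."""
        if self._Kcc is None:
            self._Kcc = gram(self.C, self.C, self.kernel)
        return self._Kcc

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Key-value container holding every model field; round-trip exact."""
        d = {
            "C": self.C.tolist(),
            "u1": self.u1.tolist(),
            "b1": float(self.b1),
            "u2": self.u2.tolist(),
            "b2": float(self.b2),
            "kernel": {"family": self.kernel.family, "g": float(self.kernel.g)},
            "gamma": float(self.gamma),
        }
        if self.alpha is not None:
            d["alpha"] = self.alpha.tolist()
        if self.beta is not None:
            d["beta"] = self.beta.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TSVMBinaryModel":
        return cls(
            C=np.asarray(d["C"], dtype=float),
            u1=np.asarray(d["u1"], dtype=float),
            b1=float(d["b1"]),
            u2=np.asarray(d["u2"], dtype=float),
            b2=float(d["b2"]),
            kernel=KernelSpec(g=d["kernel"]["g"], family=d["kernel"]["family"]),
            gamma=float(d["gamma"]),
            alpha=np.asarray(d["alpha"], dtype=float) if "alpha" in d else None,
            beta=np.asarray(d["beta"], dtype=float) if "beta" in d else None,
        )


class TrainingError(RuntimeError):
    """QP solver failure during TSVM training (carries solver status)."""


# ---------------------------------------------------------------------------
# box-constrained QP
# ---------------------------------------------------------------------------

def solve_box_qp(M: np.ndarray, q: np.ndarray, upper: float) -> np.ndarray:
    """Minimize ``0.5 x^T M x - q^T x`` subject to ``0 <= x <= upper``.

    ``M`` must be symmetric positive (semi)definite.  The problem is recast
    as bounded least squares via a Cholesky factor ``M = L L^T``:
    ``0.5 ||L^T x - L^{-1} q||^2`` has the same minimizers, and BVLS solves
    it to high accuracy.  A final active-set KKT refinement (exact equality
    solve on the free set) removes the residual solver tolerance, which the
    ill-conditioned surface-recovery step would otherwise amplify.
    """
    M = np.asarray(M, dtype=float)
    q = np.asarray(q, dtype=float)
    m = M.shape[0]
    scale = max(np.mean(np.diag(M)), 1e-30)
    L = None
    for jitter in (0.0, 1e-14, 1e-12, 1e-10, 1e-8):
        try:
            L = linalg.cholesky(M + jitter * scale * np.eye(m), lower=True)
            break
        except linalg.LinAlgError:
            continue
    if L is None:
        raise TrainingError("dual QP matrix is not positive semidefinite")
    b = linalg.solve_triangular(L, q, lower=True)
    res = lsq_linear(
        L.T, b, bounds=(0.0, upper), method="bvls", tol=1e-14, max_iter=max(50, 10 * m)
    )
    if res.status < 0:
        raise TrainingError(f"BVLS failed: status={res.status} ({res.message})")
    return _kkt_refine(M, q, upper, np.clip(res.x, 0.0, upper))


def _kkt_refine(M: np.ndarray, q: np.ndarray, upper: float, x: np.ndarray,
                tol: float = 1e-9, max_sweeps: int = 60) -> np.ndarray:
    """Polish a near-optimal box-QP point to exact KKT stationarity by
    re-solving the equality system on the guessed active/free partition."""
    for _ in range(max_sweeps):
        lo, hi = x <= tol * upper, x >= upper * (1.0 - tol)
        free = ~(lo | hi)
        xn = np.where(hi, upper, 0.0)
        if free.any():
            rhs = q[free] - M[np.ix_(free, hi)].sum(axis=1) * upper
            try:
                xn[free] = linalg.solve(M[np.ix_(free, free)], rhs, assume_a="pos")
            except linalg.LinAlgError:
                xn[free], *_ = np.linalg.lstsq(M[np.ix_(free, free)], rhs, rcond=None)
        xn = np.clip(xn, 0.0, upper)
        if np.max(np.abs(xn - x)) < 1e-14:
            return xn
        x = xn
    return x


def dual_objective(M: np.ndarray, q: np.ndarray, x: np.ndarray) -> float:
    """Wolfe dual objective ``q^T x - 0.5 x^T M x`` (to be maximized)."""
    return float(q @ x - 0.5 * x @ M @ x)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _regularized_inverse_apply(F: np.ndarray, eps_rel: float, rhs: np.ndarray) -> np.ndarray:
    """Solve ``(F^T F + eps I) z = rhs`` with a trace-scaled Tikhonov term."""
    FtF = F.T @ F
    eps = eps_rel * max(np.trace(FtF) / FtF.shape[0], 1e-30)
    return linalg.solve(FtF + eps * np.eye(FtF.shape[0]), rhs, assume_a="pos")


def train_tsvm(p: TSVMTrainingProblem, gamma: float = 1.0) -> TSVMBinaryModel:
    """Train a binary TSVM by solving the two Wolfe-dual box QPs.

    With ``H = [K(A, C) e1]`` and ``G = [K(B, C) e2]`` the duals are

        max_a  e2^T a - 0.5 a^T G (H^T H + eps I)^{-1} G^T a,  0 <= a <= c1,
        max_b  e1^T b - 0.5 b^T H (G^T G + eps I)^{-1} H^T b,  0 <= b <= c2,

    and the surfaces are recovered as ``[u1; b1] = -(H^T H + eps I)^{-1} G^T a``
    and ``[u2; b2] = (G^T G + eps I)^{-1} H^T b``.
    """
    m1, m2 = p.A.shape[0], p.B.shape[0]
    C = np.vstack([p.A, p.B])
    Kcc = gram(C, C, p.kernel)  # computed once, shared by both duals
    H = np.column_stack([Kcc[:m1, :], np.ones(m1)])
    G = np.column_stack([Kcc[m1:, :], np.ones(m2)])
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(G))):
        raise ValueError("non-finite Gram entries")

    # dual 1: alpha (length m2), surface 1
    P1 = _regularized_inverse_apply(H, p.regularizer, G.T)  # (m+1, m2)
    M1 = G @ P1
    M1 = 0.5 * (M1 + M1.T)
    alpha = solve_box_qp(M1, np.ones(m2), p.c1)
    z1 = -P1 @ alpha

    # dual 2: beta (length m1), surface 2
    P2 = _regularized_inverse_apply(G, p.regularizer, H.T)  # (m+1, m1)
    M2 = H @ P2
    M2 = 0.5 * (M2 + M2.T)
    beta = solve_box_qp(M2, np.ones(m1), p.c2)
    z2 = P2 @ beta

    return TSVMBinaryModel(
        C=C,
        u1=z1[:-1],
        b1=float(z1[-1]),
        u2=z2[:-1],
        b2=float(z2[-1]),
        kernel=p.kernel,
        gamma=gamma,
        alpha=alpha,
        beta=beta,
        _Kcc=Kcc,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

_NORM_GUARD = 1e-12  # floor for u^T K u when a surface degenerates


def _surface_norms(m: TSVMBinaryModel) -> tuple[float, float]:
    n1sq = float(m.u1 @ m.Kcc @ m.u1)
    n2sq = float(m.u2 @ m.Kcc @ m.u2)
    if n1sq <= _NORM_GUARD or n2sq <= _NORM_GUARD:
        logger.warning(
            "near-zero surface norm (u1^T K u1=%.3e, u2^T K u2=%.3e); "
            "flooring at %.0e", n1sq, n2sq, _NORM_GUARD,
        )
    return np.sqrt(max(n1sq, _NORM_GUARD)), np.sqrt(max(n2sq, _NORM_GUARD))


def _responses(m: TSVMBinaryModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw surface responses K(x, C) u_k + b_k for a batch of samples."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Kxc = gram(X, m.C, m.kernel)
    return Kxc @ m.u1 + m.b1, Kxc @ m.u2 + m.b2


def perpendicular_distances(m: TSVMBinaryModel, x: np.ndarray) -> tuple:
    """Normalized perpendicular distances ``(s1, s2)`` of ``x`` to the two
    surfaces: ``s_k = |K(x,C) u_k + b_k| / sqrt(u_k^T K(C,C) u_k)``.

    Accepts a single sample (1-D) or a batch (2-D); returns scalars or arrays
    accordingly.
    """
    r1, r2 = _responses(m, x)
    n1, n2 = _surface_norms(m)
    s1, s2 = np.abs(r1) / n1, np.abs(r2) / n2
    if np.ndim(x) == 1:
        return float(s1[0]), float(s2[0])
    return s1, s2


def predict_label(m: TSVMBinaryModel, x: np.ndarray):
    """Label by the nearer surface: +1 if s1 < s2, -1 if s2 < s1.

    Ties (``|s1 - s2| <= 1e-12``) break to +1 — a fixed, documented
    convention.
    """
    s1, s2 = perpendicular_distances(m, np.atleast_2d(np.asarray(x, dtype=float)))
    lab = np.where(s2 - s1 >= -TIE_TOL, 1, -1)
    if np.ndim(x) == 1:
        return int(lab[0])
    return lab


def _coupled_distances(m: TSVMBinaryModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two combined distances (d_plus, d_minus) feeding the ranking score.

    Each combines the two normalized surface responses with a
    ±2·cross-coupling term ``u1^T K(C,C) u2 / (n1 n2)``; a negative radicand
    (possible in floating point, the cross term is not sign-constrained) is
    clamped to 0.  The whole combination is deliberately isolated here so the
    formula can be revised without touching callers.
    """
    r1, r2 = _responses(m, x)
    n1, n2 = _surface_norms(m)
    cross = float(m.u1 @ m.Kcc @ m.u2) / (n1 * n2)
    a, b = r1 / n1, r2 / n2
    d_plus = np.sqrt(np.maximum((a + b) ** 2 + 2.0 * cross, 0.0))
    d_minus = np.sqrt(np.maximum((a - b) ** 2 - 2.0 * cross, 0.0))
    return d_plus, d_minus


def continuous_output(m: TSVMBinaryModel, x: np.ndarray):
    """Signed ranking score ``f(x) = sign * d_min * (d_min / d_max)^gamma``.

    The sign follows the nearer-surface rule: positive when the normalized
    response ratio s1/s2 < 1 (closer to the class +1 surface), zero at
    equality, negative otherwise.  Larger f(x) means stronger evidence for
    class +1; ``|f(x)| <= d_min(x)`` always since ``d_min/d_max <= 1``.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    s1, s2 = perpendicular_distances(m, X)
    d_plus, d_minus = _coupled_distances(m, X)
    d_min = np.minimum(d_plus, d_minus)
    d_max = np.maximum(d_plus, d_minus)
    mag = np.zeros_like(d_min)
    ok = d_max > 1e-15
    mag[ok] = d_min[ok] * (d_min[ok] / d_max[ok]) ** m.gamma
    sign = np.where(np.abs(s1 - s2) <= TIE_TOL, 0.0, np.where(s1 < s2, 1.0, -1.0))
    f = sign * mag
    if np.ndim(x) == 1:
        return float(f[0])
    return f
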