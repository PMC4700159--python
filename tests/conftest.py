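"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy import linalg
from scipy.optimize import minimize

from pptsvm.kernel import KernelSpec, gram
from pptsvm.tsvm import TSVMTrainingProblem, train_tsvm, _regularized_inverse_apply


def oracle_box_qp(M: np.ndarray, q: np.ndarray, upper: float, tol: float = 1e-9) -> np.ndarray:
    """Independent box-QP solve: L-BFGS-B on the dual followed by a KKT
    active-set polish (exact equality solve on the guessed free set).

    This path shares nothing with the package's BVLS-based solver beyond
    the problem matrices.
    """
    def fun(x):
        return 0.5 * x @ M @ x - q @ x

    def jac(x):
        return M @ x - q

    x = minimize(
        fun, np.full(len(q), upper / 2), jac=jac, method="L-BFGS-B",
        bounds=[(0.0, upper)] * len(q),
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 5000},
    ).x
    for _ in range(60):
        lo, hi = x <= tol, x >= upper - tol
        free = ~(lo | hi)
        xn = np.where(hi, upper, 0.0)
        if free.any():
            rhs = q[free] - M[np.ix_(free, hi)].sum(axis=1) * upper
            xn[free] = linalg.solve(M[np.ix_(free, free)], rhs, assume_a="pos")
        xn = np.clip(xn, 0.0, upper)
        if np.max(np.abs(xn - x)) < 1e-14:
            return xn
        x = xn
    return x


def random_tsvm_problem(rng, max_per_class: int = 15, dim: int = 2) -> TSVMTrainingProblem:
    """A small random binary TSVM problem for oracle comparisons.

    Kernel widths and cluster offsets are kept moderate so the Gram blocks
    stay numerically non-degenerate (no saturated or vanishing rows): on a
    dual with float-level flat directions no two independent solvers can
    agree on the recovered surfaces to 1e-6, so degenerate instances test
    the arithmetic, not the solver.
    """
    m1 = int(rng.integers(3, max_per_class + 1))
    m2 = int(rng.integers(3, max_per_class + 1))
    A = rng.normal(0, 1, (m1, dim)) + rng.uniform(-1.5, 1.5, dim)
    B = rng.normal(0, 1, (m2, dim)) + rng.uniform(-1.5, 1.5, dim)
    return TSVMTrainingProblem(
        A=A, B=B,
        c1=float(rng.choice([0.25, 1.25, 2.25])),
        c2=float(rng.choice([0.25, 1.25, 2.25])),
        kernel=KernelSpec(g=float(rng.choice([0.25, 0.5, 1.0]))),
    )


def dual_matrices(p: TSVMTrainingProblem):
    """Rebuild the two dual QP matrices (M, q, box) of a training problem,
    plus the surface-recovery operators, straight from the formulas."""
    m1 = p.A.shape[0]
    C = np.vstack([p.A, p.B])
    K = gram(C, C, p.kernel)
    H = np.column_stack([K[:m1, :], np.ones(m1)])
    G = np.column_stack([K[m1:, :], np.ones(len(C) - m1)])
    P1 = _regularized_inverse_apply(H, p.regularizer, G.T)
    M1 = G @ P1
    P2 = _regularized_inverse_apply(G, p.regularizer, H.T)
    M2 = H @ P2
    return (0.5 * (M1 + M1.T), P1, p.c1), (0.5 * (M2 + M2.T), P2, p.c2)


def random_pairwise(rng, M: int) -> np.ndarray:
    """A random valid pairwise probability matrix (r_ij + r_ji = 1)."""
    r = np.full((M, M), 0.5)
    for i in range(M):
        for j in range(i + 1, M):
            p = float(rng.uniform(0.02, 0.98))
            r[i, j], r[j, i] = p, 1.0 - p
    return r


@pytest.fixture(scope="session")
def separable_binary():
    """Two well-separated 2-D blobs, 10 points each, centers +-5."""
    rng = np.random.default_rng(7)
    A = rng.normal(0, 1, (10, 2)) + [5.0, 0.0]
    B = rng.normal(0, 1, (10, 2)) + [-5.0, 0.0]
    problem = TSVMTrainingProblem(A=A, B=B, c1=0.25, c2=0.25, kernel=KernelSpec(g=0.25))
    return problem, train_tsvm(problem)
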