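"""Gaussian kernel and Gram-matrix construction shared by all TSVM operations.

The kernel is parameterized as ``K(x, y) = exp(-g * ||x - y||^2)`` with a
single positive width parameter ``g`` — the same ``g`` that is grid-searched
alongside the penalty parameters.  (An equivalent bandwidth convention
``exp(-||x-y||^2 / (2 sigma^2))`` exists in the literature; this package fixes
the single-parameter form, so a bandwidth sigma corresponds to
``g = 1 / (2 sigma^2)``.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "gram"]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel specification.

    Parameters
    ----------
    g : float
        Positive width parameter; ``K(x, y) = exp(-g * ||x - y||^2)``.
    family : str
        Kernel family; only ``"gaussian"`` is supported.
    """

    g: float
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError(f"unsupported kernel family: {self.family!r}")
        if not np.isfinite(self.g) or self.g <= 0:
            raise ValueError(f"kernel width g must be a positive real, got {self.g}")


def gram(X: np.ndarray, Y: np.ndarray, k: KernelSpec) -> np.ndarray:
    """Gaussian Gram matrix between the rows of ``X`` and the rows of ``Y``.

    Entry ``(i, j)`` is ``exp(-g * ||X_i - Y_j||^2)``.  ``gram(X, X, k)`` is
    symmetric positive semidefinite with unit diagonal.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature dimensions differ: X has {X.shape[1]}, Y has {Y.shape[1]}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in kernel inputs")
    D = cdist(X, Y, metric="sqeuclidean")
    K = np.exp(-k.g * D)
    if X is Y or (X.shape == Y.shape and np.array_equal(X, Y)):
        # exact symmetry for the self-Gram; cdist can leave ~1e-16 asymmetry
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
    return K
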