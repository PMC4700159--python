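"""Platt sigmoid calibration: map a classifier's continuous output to a
two-class posterior probability.

The posterior model is ``p(y=+1 | f) = 1 / (1 + exp(a*f + b))`` with the two
parameters fitted by regularized maximum likelihood.  On data where larger
``f`` favors class +1 a discriminative fit yields ``a < 0``.  The fit uses
Platt's prior-corrected targets and a damped Newton iteration with the
numerically stable log-sum formulation, because the naive logistic fit
diverges on separable scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["SigmoidParams", "fit_sigmoid", "posterior"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SigmoidParams:
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("sigmoid parameters must be finite")

    def to_dict(self) -> dict:
        return {"a": float(self.a), "b": float(self.b)}

    @classmethod
    def from_dict(cls, d: dict) -> "SigmoidParams":
        return cls(a=float(d["a"]), b=float(d["b"]))


def sigmoid_deviance(f: np.ndarray, t: np.ndarray, a: float, b: float) -> float:
    """Negative log-likelihood of targets ``t`` (probability of class +1)
    under ``p(+1) = 1/(1+e^{a f + b})``.

    With z = a*f + b the per-sample term ``-t log p - (1-t) log(1-p)``
    reduces to the overflow-safe ``t*z + log(1 + e^{-z})``.
    """
    z = a * f + b
    return float(np.sum(t * z + np.logaddexp(0.0, -z)))


def fit_sigmoid(
    f: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    grad_tol: float = 1e-5,
    return_trace: bool = False,
):
    """Fit ``(a, b)`` of ``p(+1|f) = 1/(1+exp(a f + b))`` by maximum likelihood.

    Uses Platt's regularized targets ``t+ = (N+ + 1)/(N+ + 2)`` for positive
    samples and ``t- = 1/(N- + 2)`` for negatives, and a damped Newton
    iteration (backtracking halving) on the stable log-sum objective.
    Converges when the gradient infinity-norm drops below ``grad_tol`` or
    after ``max_iter`` iterations.

    With ``return_trace=True`` also returns the per-iteration deviance
    values (non-increasing by construction of the line search).
    """
    f = np.asarray(f, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite continuous outputs")
    pos = y == 1
    neg = y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos + n_neg != len(y):
        raise ValueError("labels must be +1/-1")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit the sigmoid")

    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    # optimize over z = a*f + b with w = (a, b); gradient in p - (1-t) terms
    a = 0.0
    b = np.log((n_neg + 1.0) / (n_pos + 1.0))
    obj = sigmoid_deviance(f, t, a, b)
    trace = [obj]
    for _ in range(max_iter):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        # d/dz of the per-sample NLL t*z + log(1+e^{-z}) is t - p(+1)
        d = t - p
        g_a = float(np.dot(d, f))
        g_b = float(np.sum(d))
        if max(abs(g_a), abs(g_b)) < grad_tol:
            break
        w = p * (1.0 - p)
        h_aa = float(np.dot(w, f * f)) + 1e-12
        h_ab = float(np.dot(w, f))
        h_bb = float(np.sum(w)) + 1e-12
        det = h_aa * h_bb - h_ab * h_ab
        if det <= 0:
            logger.warning("singular Hessian in sigmoid fit; stopping early")
            break
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(h_aa * g_b - h_ab * g_a) / det
        # backtracking so the deviance never increases
        step = 1.0
        for _ in range(30):
            new_obj = sigmoid_deviance(f, t, a + step * da, b + step * db)
            if new_obj <= obj + 1e-12:
                break
            step *= 0.5
        else:
            break
        a, b = a + step * da, b + step * db
        obj = new_obj
        trace.append(obj)
    if a >= 0:
        logger.warning(
            "fitted sigmoid slope a=%.4g is non-negative; the continuous "
            "output does not discriminate the classes on this data", a,
        )
    params = SigmoidParams(a=a, b=b)
    return (params, trace) if return_trace else params


def posterior(s: SigmoidParams, f):
    """Posterior pair ``(p_plus, p_minus)`` for score(s) ``f``.

    ``p_plus = 1/(1+exp(a f + b))`` computed overflow-safely;
    ``p_minus = 1 - p_plus`` exactly.
    """
    z = s.a * np.asarray(f, dtype=float) + s.b
    p_plus = np.where(z >= 0, np.exp(-np.clip(z, 0, None)) / (1.0 + np.exp(-np.clip(z, 0, None))),
                      1.0 / (1.0 + np.exp(np.clip(z, None, 0))))
    if np.ndim(f) == 0:
        p_plus = float(p_plus)
        return p_plus, 1.0 - p_plus
    return p_plus, 1.0 - p_plus
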