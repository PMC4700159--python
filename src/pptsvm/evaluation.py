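"""Evaluation: Cohen's kappa and the repeated stratified-split experiment
harness.

Kappa is the chance-corrected agreement ``(p0 - pe) / (1 - pe)`` where p0 is
the observed accuracy and pe the agreement expected by chance.  For
balanced classes ``pe = 1/M`` and kappa reduces to ``(M p0 - 1)/(M - 1)``:
50% accuracy on two classes and 25% on four classes are both kappa = 0,
making multiclass problems comparable.  For unbalanced data pe is computed
from the confusion-matrix marginals (the standard Cohen definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "kappa_general",
    "kappa_balanced",
    "kappa_score",
    "EvaluationResult",
    "repeated_split_experiment",
]

#: protocol defaults: 65:35 stratified split repeated 100 times
DEFAULT_RATIO = 0.65
DEFAULT_REPS = 100


def kappa_general(p0: float, pe: float) -> float:
    """Cohen's kappa ``(p0 - pe) / (1 - pe)``."""
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    if not 0 <= pe < 1:
        raise ValueError("pe must lie in [0, 1)")
    return (p0 - pe) / (1.0 - pe)


def kappa_balanced(p0: float, M: int) -> float:
    """Kappa under balanced classes (pe = 1/M): ``(M p0 - 1) / (M - 1)``."""
    if M < 2:
        raise ValueError("M must be >= 2")
    return (M * p0 - 1.0) / (M - 1.0)


def kappa_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Kappa from labels, with pe from the confusion-matrix marginal
    products (handles unequal class frequencies)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    n = len(y_true)
    p0 = float(np.mean(y_true == y_pred))
    pe = sum(
        float(np.sum(y_true == c)) * float(np.sum(y_pred == c)) for c in classes
    ) / (n * n)
    if pe >= 1.0:
        return 1.0 if p0 == 1.0 else 0.0  # degenerate single-class case
    return kappa_general(p0, pe)


@dataclass
class EvaluationResult:
    """Mean/sd summary plus per-repetition accuracy and kappa values."""

    accuracies: list = field(default_factory=list)
    kappas: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.kappas))

    @property
    def sd_kappa(self) -> float:
        return float(np.std(self.kappas, ddof=1)) if len(self.kappas) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "reps": len(self.accuracies),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_kappa": self.mean_kappa,
            "sd_kappa": self.sd_kappa,
        }


def repeated_split_experiment(
    X: np.ndarray,
    y: np.ndarray,
    fit_predict,
    ratio: float = DEFAULT_RATIO,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated stratified train/test evaluation.

    Per repetition: draw a stratified ``ratio`` (default 65%) training split,
    call ``fit_predict(X_train, y_train, X_test) -> y_pred``, and record test
    accuracy and kappa; the mean and standard deviation over ``reps``
    repetitions (default 100) summarize the run.  Fully reproducible from
    ``seed``.  A split missing a class is re-drawn (up to 100 attempts) —
    only possible for pathologically small classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    result = EvaluationResult()
    for _ in range(reps):
        for _attempt in range(100):
            split_seed = int(rng.integers(0, 2**31 - 1))
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, train_size=ratio, stratify=y, random_state=split_seed
            )
            if len(np.unique(y_tr)) == len(classes) and len(np.unique(y_te)) == len(classes):
                break
        else:
            raise RuntimeError("could not draw a split containing every class")
        y_pred = fit_predict(X_tr, y_tr, X_te)
        result.accuracies.append(float(np.mean(y_pred == y_te)))
        result.kappas.append(kappa_score(y_te, y_pred))
    return result
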