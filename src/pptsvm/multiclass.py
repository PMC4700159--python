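"""One-against-one multiclass posterior-probability TSVM.

Trains one binary TSVM + Platt sigmoid per unordered class pair — M(M-1)/2
models for M classes — then at prediction time estimates the pairwise
probabilities r_ij and reconciles them into a single class-probability
vector by pairwise coupling (quadratic or KL), or falls back to plain
voting.  The orchestration accepts any binary probabilistic classifier
satisfying the (train, continuous output, calibrate) contract, so SVM-style
baselines can be slotted in for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import coupling as cpl
from .calibration import SigmoidParams, fit_sigmoid, posterior
from .kernel import KernelSpec
from .tsvm import TSVMBinaryModel, TSVMTrainingProblem, continuous_output, train_tsvm

__all__ = [
    "Hyperparameters",
    "PairwiseClassifier",
    "MulticlassPPTSVM",
    "train_multiclass",
    "predict_proba",
    "predict",
    "grid_search_cv",
    "DEFAULT_GRID",
    "GEOMETRIC_GRID",
]

#: default hyperparameter grid (arithmetic, step 1.0) — the values the tuned
#: models actually land on; the power-of-two grid is available as an option
DEFAULT_GRID: tuple[float, ...] = (0.25, 1.25, 2.25, 3.25)
GEOMETRIC_GRID: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class Hyperparameters:
    """Shared hyperparameters for all pairwise models: penalties c1, c2,
    kernel width g, and the ranking-output weight gamma (default 1)."""

    c1: float = 0.25
    c2: float = 0.25
    g: float = 0.25
    gamma: float = 1.0


@dataclass
class PairwiseClassifier:
    """A binary TSVM with its Platt calibration, oriented so the pair's
    lower-index class plays +1."""

    model: TSVMBinaryModel
    sigmoid: SigmoidParams

    def prob_plus(self, X: np.ndarray) -> np.ndarray:
        f = continuous_output(self.model, np.atleast_2d(X))
        p_plus, _ = posterior(self.sigmoid, f)
        return p_plus


@dataclass
class MulticlassPPTSVM:
    """A trained one-against-one PPTSVM: M ordered class labels, one
    (model, sigmoid) pair per unordered class pair, and the configured
    coupling method ('coupling', 'coupling-kl', or 'vote')."""

    classes: np.ndarray
    pairwise: dict = field(default_factory=dict)  # (i, j) i<j -> PairwiseClassifier
    method: str = "coupling"
    hyper: Hyperparameters = field(default_factory=Hyperparameters)

    def __post_init__(self) -> None:
        if self.method not in ("coupling", "coupling-kl", "vote"):
            raise ValueError(f"unknown coupling method: {self.method!r}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _class_indices(y: np.ndarray, classes: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(y == c) for c in classes]


def train_multiclass(
    X: np.ndarray,
    y: np.ndarray,
    hp: Hyperparameters | None = None,
    method: str = "coupling",
) -> MulticlassPPTSVM:
    """Train all M(M-1)/2 pairwise PPTSVM models.

    For the pair (i, j) with i < j in the sorted class order, class i plays
    +1 and class j plays -1; the binary TSVM is trained on that pair's
    samples only and its sigmoid is fitted to the same samples' continuous
    outputs (no held-out calibration split).
    """
    hp = hp or Hyperparameters()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    idx = _class_indices(y, classes)
    for c, ix in zip(classes, idx):
        if len(ix) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")

    kernel = KernelSpec(g=hp.g)
    model = MulticlassPPTSVM(classes=classes, method=method, hyper=hp)
    for i, j in itertools.combinations(range(len(classes)), 2):
        A, B = X[idx[i]], X[idx[j]]
        prob = TSVMTrainingProblem(A=A, B=B, c1=hp.c1, c2=hp.c2, kernel=kernel)
        bin_model = train_tsvm(prob, gamma=hp.gamma)
        f_train = continuous_output(bin_model, np.vstack([A, B]))
        y_train = np.concatenate([np.ones(len(A)), -np.ones(len(B))])
        sig = fit_sigmoid(f_train, y_train)
        model.pairwise[(i, j)] = PairwiseClassifier(model=bin_model, sigmoid=sig)
    return model


def _pairwise_matrix(m: MulticlassPPTSVM, X: np.ndarray) -> np.ndarray:
    """Stack the calibrated pairwise probabilities into (n_samples, M, M)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = m.n_classes
    R = np.full((X.shape[0], M, M), 0.5)
    for (i, j), clf in m.pairwise.items():
        p = np.clip(clf.prob_plus(X), 1e-12, 1.0 - 1e-12)
        R[:, i, j] = p
        R[:, j, i] = 1.0 - p
    return R


def predict_proba(m: MulticlassPPTSVM, x: np.ndarray) -> np.ndarray:
    """Class-probability vector(s) for sample(s) ``x``.

    Pairwise probabilities come from each pair's calibrated model
    (``r_ji = 1 - r_ij``); they are coupled by the configured method.  For
    ``method='vote'`` the result is the one-hot vector of the vote winner.
    Rows lie on the probability simplex.
    """
    single = np.ndim(x) == 1
    R = _pairwise_matrix(m, x)
    M = m.n_classes
    out = np.empty((R.shape[0], M))
    for s in range(R.shape[0]):
        if m.method == "coupling":
            out[s] = cpl.solve_coupling(cpl.build_Q(R[s]))
        elif m.method == "coupling-kl":
            out[s] = cpl.solve_coupling_kl(R[s])
        else:
            out[s] = np.eye(M)[cpl.vote(R[s])]
    return out[0] if single else out


def predict(m: MulticlassPPTSVM, x: np.ndarray):
    """Predicted class label(s): argmax of the coupled probabilities, ties
    to the lowest class index."""
    P = np.atleast_2d(predict_proba(m, x))
    lab = m.classes[np.argmax(P, axis=1)]
    return lab[0] if np.ndim(x) == 1 else lab


# ---------------------------------------------------------------------------
# hyperparameter selection
# ---------------------------------------------------------------------------

def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] = DEFAULT_GRID,
    k: int = 10,
    method: str = "coupling",
    seed: int = 0,
    gamma: float = 1.0,
    trainer: Callable | None = None,
) -> tuple[Hyperparameters, list[dict]]:
    """Stratified k-fold cross-validated grid search over (c1, c2, g).

    Every grid point is scored by mean CV accuracy; the winner is the argmax
    with deterministic tie-breaking (smallest c1, then c2, then g).  Folds
    are generated from the explicit ``seed``.  Returns the selected
    hyperparameters and the full accuracy table (one dict per grid point).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size ({counts.min()}); "
            f"use k <= {counts.min()} (e.g. 2-fold for very small classes)"
        )
    trainer = trainer or train_multiclass
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    table: list[dict] = []
    for c1 in grid:
        for c2 in grid:
            for g in grid:
                hp = Hyperparameters(c1=c1, c2=c2, g=g, gamma=gamma)
                accs = []
                for tr, te in folds:
                    m = trainer(X[tr], y[tr], hp=hp, method=method)
                    accs.append(float(np.mean(predict(m, X[te]) == y[te])))
                table.append({"c1": c1, "c2": c2, "g": g, "cv_accuracy": float(np.mean(accs))})
    best = max(table, key=lambda row: (row["cv_accuracy"], -row["c1"], -row["c2"], -row["g"]))
    hp_best = Hyperparameters(c1=best["c1"], c2=best["c2"], g=best["g"], gamma=gamma)
    return hp_best, table
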