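"""EEG front-end: Butterworth band-pass filtering and one-vs-rest common
spatial patterns (CSP) with log-variance features.

CSP finds spatial filters w maximizing the variance ratio between two trial
populations; the one-vs-rest (OVR) extension fits one filter bank per class
against the pooled remaining classes.  For each class the generalized
eigenproblem ``R_m w = lambda (R_m + R_rest) w`` is solved on averaged
trace-normalized spatial covariances, and the J eigenvectors of largest plus
J of smallest eigenvalue form the class's 2J-row projection matrix.  Each
trial is then summarized by normalized log-variance band-power features

    f_p = log( var(Z_p) / sum_{j=1..2J} var(Z_j) ),   Z = W_m X,

concatenated over the M classes into a 2*J*M-dimensional feature vector.
With M=4 classes and J=2 filters per side this is the familiar
16-dimensional motor-imagery feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

__all__ = ["EEGEpochs", "CSPModel", "bandpass", "fit_ovr_csp", "extract_features"]

logger = logging.getLogger(__name__)

#: band and filter order of the standard motor-imagery preprocessing
DEFAULT_BAND = (7.0, 35.0)
DEFAULT_ORDER = 5


@dataclass
class EEGEpochs:
    """Epoched multichannel EEG: ``data`` is (trials, channels, samples) at
    sampling rate ``fs`` with one class label per trial."""

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 channels")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if np.any(~np.isfinite(self.data)):
            raise ValueError("NaN/inf in EEG data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class CSPModel:
    """Per-class OVR-CSP projections: ``filters[m]`` is (2J, channels) for
    each of the M classes in ``classes`` order; features are 2*J*M long."""

    classes: np.ndarray
    filters: list = field(default_factory=list)
    J: int = 2

    @property
    def n_features(self) -> int:
        return 2 * self.J * len(self.classes)


def bandpass(
    e: EEGEpochs,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> EEGEpochs:
    """Zero-phase Butterworth band-pass (forward-backward) per channel/trial.

    Defaults to the 7-35 Hz order-5 filter spanning the mu and beta bands
    relevant to motor imagery.  Forward-backward application doubles the
    effective order but leaves no phase distortion, which matters for
    variance-based features.
    """
    nyq = e.fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist ({nyq} Hz)")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=e.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, e.data, axis=-1)
    return EEGEpochs(data=filtered, fs=e.fs, labels=e.labels, channel_names=e.channel_names)


def _mean_normalized_cov(trials: np.ndarray) -> np.ndarray:
    """Average of per-trial spatial covariances X X^T / trace(X X^T)."""
    covs = np.einsum("tcs,tds->tcd", trials, trials)
    traces = np.trace(covs, axis1=1, axis2=2)
    return np.mean(covs / traces[:, None, None], axis=0)


def fit_ovr_csp(e: EEGEpochs, J: int = 2) -> CSPModel:
    """Fit one-vs-rest CSP filters, J per side, for every class.

    For class m, solves ``R_m w = lambda (R_m + R_rest) w`` where R_m and
    R_rest are averaged trace-normalized spatial covariances of the class-m
    and pooled remaining trials.  The composite covariance is regularized by
    ``delta*I`` (delta = 1e-9 * trace/channels) if rank-deficient.  The
    eigenvalues lie in [0, 1]; W_m keeps the J largest- and J
    smallest-eigenvalue eigenvectors (rows), the directions where class m is
    maximally high- or low-variance relative to the rest.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if 2 * J > e.n_channels:
        raise ValueError(f"2J={2*J} spatial filters exceed {e.n_channels} channels")
    classes = np.unique(e.labels)
    for c in classes:
        if np.sum(e.labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")

    filters = []
    for c in classes:
        own = e.data[e.labels == c]
        rest = e.data[e.labels != c]
        R_own = _mean_normalized_cov(own)
        R_rest = _mean_normalized_cov(rest)
        composite = R_own + R_rest
        # regularize a rank-deficient composite so the pencil is definite
        eigmin = linalg.eigvalsh(composite)[0]
        if eigmin < 1e-10 * np.trace(composite) / e.n_channels:
            delta = 1e-9 * np.trace(composite) / e.n_channels
            logger.warning("rank-deficient composite covariance; adding %.2e*I", delta)
            composite = composite + delta * np.eye(e.n_channels)
        lam, vecs = linalg.eigh(R_own, composite)
        order = np.argsort(lam)
        keep = np.concatenate([order[-J:][::-1], order[:J]])  # J largest, J smallest
        filters.append(vecs[:, keep].T.copy())
    return CSPModel(classes=classes, filters=filters, J=J)


def extract_features(model: CSPModel, e: EEGEpochs) -> np.ndarray:
    """Normalized log-variance CSP features, (trials, 2*J*M).

    Per trial and class-m projection ``Z = W_m X``:
    ``f_p = log(var(Z_p) / sum_j var(Z_j))`` over the 2J projected signals;
    blocks are concatenated over classes.  The within-block normalization
    makes features invariant to any positive rescaling of the trial.
    """
    if model.filters[0].shape[1] != e.n_channels:
        raise ValueError("channel count does not match the fitted model")
    feats = []
    for W in model.filters:
        Z = np.einsum("jc,tcs->tjs", W, e.data)
        v = np.var(Z, axis=-1)
        v = np.maximum(v, 1e-300)  # floor: a projected signal can be exactly flat
        feats.append(np.log(v / v.sum(axis=1, keepdims=True)))
    return np.concatenate(feats, axis=1)
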