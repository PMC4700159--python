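"""Synthetic fixtures: multiclass Gaussian feature blobs and EEG-like
epochs with class-dependent spatial covariance.

Both generators are pure functions of their spec (seed included), so every
downstream stage is testable without external downloads.  The EEG generator
mimics the shape of a standard four-class motor-imagery recording — 22
channels sampled at 250 Hz — but produces stationary band-limited sources,
not physiologically realistic EEG (no ERD/ERS dynamics, no artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .csp import EEGEpochs

__all__ = ["BlobSpec", "make_blobs", "SynthEEGSpec", "make_synth_eeg"]


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian-blob dataset spec.

    ``centers`` may be given explicitly (M x dim); otherwise they are placed
    automatically with minimum pairwise distance ``separation * sigma``:
    a regular simplex when ``dim >= M - 1``, else evenly spaced on a circle
    in the first two dimensions.
    """

    M: int = 4
    n_per_class: int = 40
    dim: int = 2
    separation: float = 6.0
    sigma: float = 1.0
    centers: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2 or self.n_per_class < 1 or self.dim < 1:
            raise ValueError("invalid blob spec")
        if self.separation <= 0 or self.sigma <= 0:
            raise ValueError("separation and sigma must be positive")


def _auto_centers(M: int, dim: int, dist: float) -> np.ndarray:
    if dim >= M - 1:
        # regular simplex: centered standard basis has pairwise distance
        # sqrt(2); rotate into its (M-1)-dim span and rescale to dist
        V = np.eye(M) - 1.0 / M
        coords = V @ np.linalg.svd(V)[2].T[:, : M - 1]
        coords *= dist / np.sqrt(2.0)
        C = np.zeros((M, dim))
        C[:, : M - 1] = coords
        return C
    # circle placement: chord between neighbors equals dist
    radius = dist / (2.0 * np.sin(np.pi / M))
    ang = 2.0 * np.pi * np.arange(M) / M
    C = np.zeros((M, dim))
    C[:, 0] = radius * np.cos(ang)
    C[:, 1 % dim] = radius * np.sin(ang)
    return C


def make_blobs(s: BlobSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the blob dataset; returns ``(X, y)`` with exact class counts,
    deterministic from ``s.seed``."""
    rng = np.random.default_rng(s.seed)
    if s.centers is not None:
        centers = np.asarray(s.centers, dtype=float)
        if centers.shape != (s.M, s.dim):
            raise ValueError("centers must be M x dim")
    else:
        centers = _auto_centers(s.M, s.dim, s.separation * s.sigma)
    X = np.vstack([
        centers[m] + s.sigma * rng.standard_normal((s.n_per_class, s.dim))
        for m in range(s.M)
    ])
    y = np.repeat(np.arange(s.M), s.n_per_class)
    return X, y


@dataclass(frozen=True)
class SynthEEGSpec:
    """EEG-like epoch generator spec.

    Each trial is built from ``channels`` latent band-limited sources (white
    noise band-passed to ``band``), scaled per class by a variance profile,
    mixed into sensors by a fixed random orthogonal matrix, plus broadband
    sensor noise.  Default variance profiles give each class one dominant
    source (power ``source_boost``) over a unit-variance background — a
    crude stand-in for class-specific sensorimotor band-power topographies.
    """

    M: int = 4
    trials_per_class: int = 40
    channels: int = 22
    fs: float = 250.0
    duration_s: float = 2.0
    band: tuple = (7.0, 35.0)
    source_boost: float = 6.0
    noise_level: float = 0.5
    seed: int = 0
    variance_profiles: np.ndarray | None = None  # (M, channels) source variances

    def __post_init__(self) -> None:
        if self.channels < 2 or self.M < 2 or self.trials_per_class < 1:
            raise ValueError("invalid EEG spec")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")
        if not self.fs > 0 or not self.duration_s > 0:
            raise ValueError("fs and duration must be positive")


def _profiles(s: SynthEEGSpec) -> np.ndarray:
    if s.variance_profiles is not None:
        prof = np.asarray(s.variance_profiles, dtype=float)
        if prof.shape != (s.M, s.channels):
            raise ValueError("variance_profiles must be M x channels")
        return prof
    prof = np.ones((s.M, s.channels))
    for m in range(s.M):
        prof[m, m % s.channels] = s.source_boost
    return prof


def make_synth_eeg(s: SynthEEGSpec) -> EEGEpochs:
    """Generate EEG-like epochs, byte-deterministic from ``s.seed``."""
    rng = np.random.default_rng(s.seed)
    n_samp = int(round(s.fs * s.duration_s))
    sos = signal.butter(4, list(s.band), btype="bandpass", fs=s.fs, output="sos")
    mixing = np.linalg.qr(rng.standard_normal((s.channels, s.channels)))[0]
    prof = _profiles(s)
    n_trials = s.M * s.trials_per_class
    data = np.empty((n_trials, s.channels, n_samp))
    labels = np.repeat(np.arange(s.M), s.trials_per_class)
    for t in range(n_trials):
        src = signal.sosfilt(sos, rng.standard_normal((s.channels, n_samp)), axis=-1)
        src /= np.maximum(src.std(axis=-1, keepdims=True), 1e-12)
        src *= np.sqrt(prof[labels[t]])[:, None]
        x = mixing @ src
        if s.noise_level > 0:
            x = x + s.noise_level * rng.standard_normal((s.channels, n_samp))
        data[t] = x
    return EEGEpochs(data=data, fs=s.fs, labels=labels)
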