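"""Seeded generators of manifold-structured synthetic data.

These stand in for the feature matrices the pipeline is designed for —
hidden-layer activations of a network paired with continuous targets, or
expression-like continua — so that every stage can be exercised and
benchmarked without external data.  A one-dimensional latent parameter t
drives a smooth random-Fourier curve in feature space ("trained"-like
features carry the latent ordering; "untrained" ones are independent
noise of the same shape).

All generators are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SyntheticDataset", "make_curve", "make_layer_features", "make_blobs"]


class SynthError(ValueError):
    """Invalid generator arguments."""


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated dataset with its latent parameter and targets.

    Attributes
    ----------
    X : ndarray (n_samples, n_features)
    t : ndarray (n_samples,) or (n_samples, 2)
        Latent manifold parameter.
    y : ndarray
        Targets: continuous (equal to t for curves) or integer class labels.
    regime : {"trained", "untrained"}
        Whether X is a smooth function of t or independent of it.
    noise_sd : float
    seed : int
    """

    X: np.ndarray
    t: np.ndarray
    y: np.ndarray
    regime: str
    noise_sd: float
    seed: int


def _fourier_lift(t: np.ndarray, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth curve in `dim` dimensions: low-order Fourier series of t.

    Coefficients decay with frequency so the curve bends gently and stays
    injective in high dimensions; columns are scaled to unit RMS so a
    noise_sd of s reads as noise at fraction s of signal scale.
    """
    n_freq = 3
    freqs = np.arange(1, n_freq + 1)
    a = rng.normal(size=(dim, n_freq)) / freqs
    b = rng.normal(size=(dim, n_freq)) / freqs
    phase = np.pi * freqs[None, :] * t[:, None]  # n x n_freq
    X = np.cos(phase) @ a.T + np.sin(phase) @ b.T
    X = X - X.mean(axis=0)
    rms = np.sqrt(np.mean(X**2, axis=0))
    rms = np.where(rms < 1e-12, 1.0, rms)
    return X / rms


def make_curve(n: int, dim: int, noise_sd: float = 0.0, seed: int = 0) -> SyntheticDataset:
    """1-D latent curve: t ~ Uniform(0,1), X = smooth lift of t plus noise, y = t."""
    if n < 10:
        raise SynthError("need n >= 10")
    if dim < 3:
        raise SynthError("need dim >= 3")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n)
    X = _fourier_lift(t, dim, rng)
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return SyntheticDataset(X=X, t=t, y=t.copy(), regime="trained",
                            noise_sd=noise_sd, seed=seed)


def make_layer_features(
    base: SyntheticDataset, regime: str, seed: int = 0
) -> SyntheticDataset:
    """Feature matrix emulating a network layer for the base dataset.

    "trained": a fresh smooth invertible re-embedding of the base latent
    parameter (the layer has learned the manifold); "untrained": a matrix
    of the same shape statistically independent of the latent parameter.
    """
    if regime not in ("trained", "untrained"):
        raise SynthError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    t = np.asarray(base.t, dtype=float)
    n, dim = base.X.shape
    if regime == "trained":
        X = _fourier_lift(t, dim, rng)
        if base.noise_sd > 0:
            X = X + rng.normal(0.0, base.noise_sd, size=X.shape)
    else:
        X = rng.normal(size=(n, dim))
    return SyntheticDataset(X=X, t=t.copy(), y=base.y.copy(), regime=regime,
                            noise_sd=base.noise_sd, seed=seed)


def make_blobs(
    n: int, dim: int, n_classes: int, sep: float = 3.0, seed: int = 0
) -> SyntheticDataset:
    """Gaussian class blobs with unit within-class standard deviation.

    Class means are placed so every pair of means is (approximately) `sep`
    apart, i.e. separation is in units of the common standard deviation.
    Class sizes are balanced to within one sample.
    """
    if n_classes < 2:
        raise SynthError("need n_classes >= 2")
    if n < n_classes:
        raise SynthError("need n >= n_classes")
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(max(n_classes, 1), dim))
    if dim >= n_classes:
        q, _ = np.linalg.qr(g.T)
        dirs = q[:, :n_classes].T  # orthonormal rows
    else:
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        dirs = g / np.where(norm < 1e-12, 1.0, norm)
    means = dirs * (sep / np.sqrt(2.0))  # orthonormal rows -> pairwise dist = sep
    counts = np.full(n_classes, n // n_classes)
    counts[: n % n_classes] += 1
    y = np.repeat(np.arange(1, n_classes + 1), counts)
    X = means[y - 1] + rng.normal(size=(n, dim))
    t = y.astype(float)
    return SyntheticDataset(X=X, t=t, y=y, regime="trained", noise_sd=1.0, seed=seed)
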