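"""Kernel herding sketches of cell neighborhoods.

A sketch is a small subset of rows whose kernel mean embedding tracks the
full data set's, so cell-state frequencies are preserved with far fewer
points than uniform subsampling. The Gaussian kernel is approximated with
random Fourier features; herding then greedily picks, at every step, the
unchosen row best aligned with the residual between the empirical mean
embedding and the running sample mean (Chen-Welling update).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_RFF_DIM = 2000


@dataclass
class SketchIndex:
    """Indices of the herded rows plus the kernel configuration used."""

    indices: np.ndarray
    m: int
    kernel_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ParameterError("sketch indices must be unique")
        if self.m != len(self.indices):
            raise ParameterError("m does not match number of indices")


def median_heuristic_bandwidth(Z: np.ndarray, rng: np.random.Generator, subsample: int = 1000) -> float:
    """Gaussian-kernel bandwidth: median pairwise distance on a subsample."""
    n = Z.shape[0]
    if n > subsample:
        sub = Z[rng.choice(n, size=subsample, replace=False)]
    else:
        sub = Z
    d2 = np.sum(sub**2, axis=1)
    sq = d2[:, None] + d2[None, :] - 2.0 * (sub @ sub.T)
    np.maximum(sq, 0.0, out=sq)
    dists = np.sqrt(sq[np.triu_indices_from(sq, k=1)])
    med = float(np.median(dists))
    return med if med > 0 else 1.0


def random_fourier_features(
    Z: np.ndarray, n_features: int, bandwidth: float, rng: np.random.Generator
) -> np.ndarray:
    """Map rows of Z into an RFF embedding of the Gaussian kernel.

    phi(z) = sqrt(2/D) cos(Omega z + b) with Omega ~ N(0, 1/bandwidth^2).
    """
    d = Z.shape[1]
    omega = rng.standard_normal((d, n_features)) / bandwidth
    b = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
    return np.sqrt(2.0 / n_features) * np.cos(Z @ omega + b)


def kernel_herd_sketch(
    Z: np.ndarray,
    m: int,
    seed: int = 0,
    n_rff: int = DEFAULT_RFF_DIM,
) -> SketchIndex:
    """Select m representative rows of Z by greedy kernel herding.

    Parameters
    ----------
    Z
        ``(n, d)`` matrix of cell-neighborhood profiles.
    m
        Sketch size, 1 <= m <= n. ``m == n`` returns the identity sketch.
    seed
        Seeds both the random feature map and the bandwidth subsample.
    n_rff
        Dimension of the random Fourier feature map.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if m < 1:
        raise ParameterError("sketch size m must be >= 1")
    if m > n:
        raise ParameterError(f"sketch size m={m} exceeds number of rows n={n}")
    if m == n:
        logger.warning("sketch size equals data size; returning the identity sketch")
        return SketchIndex(indices=np.arange(n), m=n, kernel_params={"identity": True, "seed": seed})

    rng = np.random.default_rng(seed)
    bandwidth = median_heuristic_bandwidth(Z, rng)
    Phi = random_fourier_features(Z, n_rff, bandwidth, rng)
    mu = Phi.mean(axis=0)  # empirical kernel mean embedding

    # Chen-Welling herding: w_0 = mu; pick argmax <w_t, phi(x)>; w <- w + mu - phi(x_t)
    w = mu.copy()
    chosen = np.zeros(n, dtype=bool)
    indices = np.empty(m, dtype=int)
    scores = Phi @ w
    phi_mu = Phi @ mu
    for t in range(m):
        scores_masked = np.where(chosen, -np.inf, scores)
        pick = int(np.argmax(scores_masked))
        indices[t] = pick
        chosen[pick] = True
        # incremental score update for w <- w + mu - phi(pick)
        scores = scores + phi_mu - Phi @ Phi[pick]
    return SketchIndex(
        indices=indices,
        m=m,
        kernel_params={"n_rff": n_rff, "bandwidth": bandwidth, "seed": seed},
    )


def mmd_rff(Phi_a: np.ndarray, Phi_b: np.ndarray) -> float:
    """Maximum mean discrepancy between two samples in a shared RFF map."""
    return float(np.linalg.norm(Phi_a.mean(axis=0) - Phi_b.mean(axis=0)))
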