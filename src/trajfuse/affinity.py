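"""Locally-scaled Gaussian affinity graphs.

Similarity between images (or points) i and j is

    w_ij = exp(-||x_i - x_j||^2 / (sigma_i * sigma_j)),

a self-tuning Gaussian kernel: each point's bandwidth sigma_i is the mean
distance to its k nearest neighbours (k = 10 by default), so the kernel
adapts to local sampling density.  Rescaling all feature vectors by a
constant rescales distances and sigmas alike and leaves W unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["AffinityMatrix", "pairwise_distances", "local_scales", "gaussian_affinity",
           "build_affinity"]

_METRICS = {"euclidean": "euclidean", "one-norm": "cityblock", "cityblock": "cityblock"}


@dataclass
class AffinityMatrix:
    """Symmetric affinity matrix with its local scales.

    Invariants: ``W == W.T``, unit diagonal, entries in (0, 1],
    ``sigmas > 0``.
    """

    W: np.ndarray
    sigmas: np.ndarray
    metric: str = "euclidean"

    @property
    def n(self) -> int:
        return self.W.shape[0]


def pairwise_distances(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Dense symmetric distance matrix between the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n points x d features)")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; use 'euclidean' or 'one-norm'")
    return squareform(pdist(X, metric=_METRICS[metric]))


def local_scales(D: np.ndarray, k: int = 10) -> np.ndarray:
    """Per-point bandwidths: mean distance to the k nearest neighbours.

    The self-distance is excluded (it would bias every scale toward
    zero).  A zero scale — possible when a point has k exact duplicates —
    is replaced by the smallest positive scale, with a warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n <= k:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    # drop the self-distance column after a stable sort (ties by index)
    order = np.argsort(D, axis=1, kind="stable")
    sigmas = np.empty(n)
    for i in range(n):
        nn = [j for j in order[i] if j != i][:k]
        sigmas[i] = D[i, nn].mean()
    if np.any(sigmas == 0):
        pos = sigmas[sigmas > 0]
        if pos.size == 0:
            raise ValueError("all points coincide; affinity graph undefined")
        warnings.warn(
            f"{int(np.sum(sigmas == 0))} local scale(s) were zero "
            "(duplicate points); replaced by the smallest positive scale",
            RuntimeWarning,
        )
        sigmas[sigmas == 0] = pos.min()
    return sigmas


def gaussian_affinity(D: np.ndarray, sigmas: np.ndarray,
                      metric: str = "euclidean") -> AffinityMatrix:
    """w_ij = exp(-d_ij^2 / (sigma_i sigma_j))."""
    D = np.asarray(D, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    W = np.exp(-(D ** 2) / np.outer(sigmas, sigmas))
    np.fill_diagonal(W, 1.0)
    # symmetrise away rounding asymmetry from the outer product
    W = 0.5 * (W + W.T)
    return AffinityMatrix(W=W, sigmas=sigmas, metric=metric)


def build_affinity(X: np.ndarray, k: int = 10,
                   metric: str = "euclidean") -> AffinityMatrix:
    """Distances -> local scales -> Gaussian affinity, in one call."""
    D = pairwise_distances(X, metric=metric)
    sig = local_scales(D, k=k)
    return gaussian_affinity(D, sig, metric=metric)
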