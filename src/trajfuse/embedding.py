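"""Diffusion-map embedding of the affinity graph, for manifold inspection.

The embedding coordinates are the leading non-trivial right eigenvectors
of the row-normalized matrix P = D^{-1} W, each scaled by its eigenvalue
(diffusion time 1).  On data sampled from a one-dimensional trajectory
the first coordinate orders the points along it, which is a useful
visual check that the affinity graph captured the latent dynamics.

Outlier filtering (points whose nearest-neighbour distance is at least
``factor`` times the median nearest-neighbour distance) is provided for
visualisation only; it is deliberately separate from the fusion graph,
which always keeps every point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

__all__ = ["Embedding", "diffusion_map", "filter_outliers"]


@dataclass
class Embedding:
    coordinates: np.ndarray     # (n, n_components)
    eigenvalues: np.ndarray     # (n_components,) descending, trivial excluded


def diffusion_map(W: np.ndarray, n_components: int = 3) -> Embedding:
    """Top non-trivial diffusion coordinates of the graph.

    Solves the symmetrised eigenproblem of D^{-1/2} W D^{-1/2} (same
    spectrum as D^{-1} W) and converts eigenvectors back, excluding the
    trivial constant one.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    mask = W > 1e-12
    np.fill_diagonal(mask, True)
    n_comp, comp = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(mask), directed=False)
    if n_comp > 1:
        comps = [list(map(int, np.flatnonzero(comp == c))) for c in range(n_comp)]
        raise ValueError(f"graph is disconnected; components: {comps}")

    d = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    A = inv_sqrt[:, None] * W * inv_sqrt[None, :]
    k = min(n_components + 1, n)
    evals, evecs = scipy.linalg.eigh(A, subset_by_index=(n - k, n - 1))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the trivial eigenvalue-1 component; map back to right eigenvectors
    psi = inv_sqrt[:, None] * evecs[:, 1:]
    lam = evals[1:]
    # normalise each coordinate then scale by its eigenvalue
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    coords = psi * lam[None, :]
    return Embedding(coordinates=coords, eigenvalues=lam)


def filter_outliers(D: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Keep-mask: drop points whose nearest-neighbour distance is at
    least ``factor`` times the median nearest-neighbour distance."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    off = D + np.diag(np.full(n, np.inf))
    nn = off.min(axis=1)
    med = np.median(nn)
    if not np.isfinite(factor):
        return np.ones(n, dtype=bool)
    return nn < factor * med
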