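"""Harmonic extension of labels on a similarity graph.

The semi-supervised matrix-completion step: given a symmetric affinity
matrix ``W`` over ``n = l + u`` points and labels ``Y`` on a subset
``Omega`` of ``l`` points, the missing values minimise the graph
Dirichlet energy

    E(f) = sum_ij w_ij * ||f_i - f_j||^2,    f_i = y_i on Omega,

whose unique minimiser on a connected graph is the harmonic extension

    f_u = (D_u - W_uu)^{-1} W_ul Y,

with d_i = sum_j w_ij, ``D_u`` the diagonal degree matrix over unlabeled
points, ``W_uu`` the unlabeled block and ``W_ul`` the unlabeled-by-labeled
block.  Vector-valued labels (one column per pixel, say) are handled
column-independently: the Euclidean norm in the objective decomposes
across coordinates, so a single factorisation serves every column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

__all__ = [
    "ModalityLabels",
    "CompletedTrajectory",
    "DisconnectedGraphError",
    "harmonic_extension",
    "label_propagation",
    "complete_study",
    "dirichlet_energy",
]

#: affinities below this are treated as absent when checking connectivity
CONNECTIVITY_EPS = 1e-12


class DisconnectedGraphError(RuntimeError):
    """Raised when unlabeled points cannot reach any labeled point."""

    def __init__(self, components):
        self.components = components
        msg = "; ".join(
            f"component {sorted(c)} has no labeled point" for c in components
        )
        super().__init__(f"graph is disconnected from the labeled set: {msg}")


@dataclass
class ModalityLabels:
    """Labels for one target modality (a molecular channel, or time).

    Parameters
    ----------
    name : str
        Modality name, e.g. ``"dpERK"`` or ``"time"``.
    labeled_idx : array of int
        Indices (into the full point set) of the labeled points, the set
        Omega(m).  No duplicates.
    Y : array, shape (l,) or (l, p)
        Label values; ``p`` is 1 for scalars such as time, or the pixel
        count for image-valued modalities.
    """

    name: str
    labeled_idx: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        self.labeled_idx = np.asarray(self.labeled_idx, dtype=int)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.labeled_idx.ndim != 1:
            raise ValueError("labeled_idx must be one-dimensional")
        if self.labeled_idx.size == 0:
            raise ValueError(f"modality {self.name!r}: empty labeled set")
        if np.unique(self.labeled_idx).size != self.labeled_idx.size:
            raise ValueError(f"modality {self.name!r}: duplicate labeled indices")
        if self.Y.shape[0] != self.labeled_idx.size:
            raise ValueError(
                f"modality {self.name!r}: Y has {self.Y.shape[0]} rows for "
                f"{self.labeled_idx.size} labeled points"
            )
        if not np.all(np.isfinite(self.Y)):
            raise ValueError(f"modality {self.name!r}: non-finite labels")

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_idx.size)


@dataclass
class CompletedTrajectory:
    """Per-modality result: observed rows copied, unlabeled rows estimated."""

    name: str
    values: np.ndarray          # (n,) or (n, p)
    labeled_idx: np.ndarray
    labeled_mask: np.ndarray = field(init=False)

    def __post_init__(self):
        n = self.values.shape[0]
        self.labeled_mask = np.zeros(n, dtype=bool)
        self.labeled_mask[self.labeled_idx] = True

    @property
    def estimated(self) -> np.ndarray:
        return self.values[~self.labeled_mask]


def _check_connectivity(W: np.ndarray, labeled_idx: np.ndarray) -> None:
    mask = W > CONNECTIVITY_EPS
    np.fill_diagonal(mask, False)
    n_comp, comp = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(mask), directed=False
    )
    labeled_comps = set(comp[labeled_idx])
    bad = [np.flatnonzero(comp == c) for c in range(n_comp) if c not in labeled_comps]
    if bad:
        raise DisconnectedGraphError([list(map(int, b)) for b in bad])


def harmonic_extension(W: np.ndarray, labels: ModalityLabels) -> CompletedTrajectory:
    """Fill in a modality's missing values by harmonic extension.

    Returns a :class:`CompletedTrajectory` whose rows at the labeled
    indices equal ``Y`` exactly and whose estimated rows obey the maximum
    principle (each column stays within the range of its labels on a
    connected graph).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("W must be square")
    if np.any(labels.labeled_idx >= n) or np.any(labels.labeled_idx < 0):
        raise ValueError("labeled index out of range")

    Y = labels.Y
    squeeze = Y.ndim == 1
    Ymat = Y[:, None] if squeeze else Y

    lab = labels.labeled_idx
    unl = np.setdiff1d(np.arange(n), lab)
    out = np.empty((n, Ymat.shape[1]))
    out[lab] = Ymat

    if unl.size:
        _check_connectivity(W, lab)
        d = W.sum(axis=1)
        A = np.diag(d[unl]) - W[np.ix_(unl, unl)]
        B = W[np.ix_(unl, lab)]
        rhs = B @ Ymat
        try:
            # A is symmetric positive definite once the graph is connected
            c, low = scipy.linalg.cho_factor(A)
            fu = scipy.linalg.cho_solve((c, low), rhs)
        except np.linalg.LinAlgError:
            eps = 1e-10 * np.trace(A) / max(A.shape[0], 1)
            warnings.warn(
                "near-singular Laplacian block; regularising with "
                f"eps={eps:.3e}", RuntimeWarning,
            )
            fu = scipy.linalg.solve(A + eps * np.eye(A.shape[0]), rhs,
                                    assume_a="pos")
        out[unl] = fu

    if squeeze:
        out = out[:, 0]
    return CompletedTrajectory(labels.name, out, lab)


def label_propagation(
    W: np.ndarray,
    labels: ModalityLabels,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> CompletedTrajectory:
    """Iterative clamped neighbourhood averaging.

    Repeats ``f_i <- sum_j w_ij f_j / d_i`` on unlabeled points with the
    labels held fixed; the fixed point is the harmonic extension.  Kept
    as the slow, transparent counterpart of the closed-form solver.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    Y = labels.Y
    squeeze = Y.ndim == 1
    Ymat = Y[:, None] if squeeze else Y

    lab = labels.labeled_idx
    unl = np.setdiff1d(np.arange(n), lab)
    _check_connectivity(W, lab)

    f = np.zeros((n, Ymat.shape[1]))
    f[lab] = Ymat
    if unl.size:
        f[unl] = Ymat.mean(axis=0)
        d = W.sum(axis=1)[unl]
        Wu = W[unl]
        for _ in range(max_iter):
            new = (Wu @ f) / d[:, None]
            delta = np.max(np.abs(new - f[unl]))
            f[unl] = new
            scale = max(np.max(np.abs(f)), 1.0)
            if delta <= tol * scale:
                break
        else:
            warnings.warn("label propagation did not converge", RuntimeWarning)

    if squeeze:
        f = f[:, 0]
    return CompletedTrajectory(labels.name, f, lab)


def complete_study(W: np.ndarray, all_labels: list[ModalityLabels]) -> list[CompletedTrajectory]:
    """Harmonic extension for every modality over one shared graph.

    Each modality has its own labeled set, hence its own factorisation;
    within a modality the factorisation is shared by all label columns
    (harmonic_extension already solves all right-hand sides at once).
    """
    return [harmonic_extension(W, labels) for labels in all_labels]


def dirichlet_energy(W: np.ndarray, f: np.ndarray) -> float:
    """The quadratic objective sum_ij w_ij * ||f_i - f_j||^2."""
    f = np.asarray(f, dtype=float)
    if f.ndim == 1:
        f = f[:, None]
    sq = ((f[:, None, :] - f[None, :, :]) ** 2).sum(axis=2)
    return float(np.sum(W * sq))
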