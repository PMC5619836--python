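"""K-fold cross-validation of harmonic extension with the normalized
absolute error (NAE).

Labeled points are partitioned at random into K bins; each bin in turn
is artificially unlabeled and its labels predicted by harmonic extension
over the full graph — crucially, the genuinely unlabeled points stay in
the graph, which is why adding unlabeled data reduces the error.  The
absolute prediction error is normalized by the signal range of the
channel computed over the entire labeled set, and (for image-valued
modalities) averaged over all pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonic import ModalityLabels, harmonic_extension

__all__ = ["CVResult", "normalized_absolute_error", "choose_K", "kfold_cv",
           "error_vs_unlabeled"]


@dataclass
class CVResult:
    """Cross-validation errors for one modality."""

    modality: str
    K: int
    repetitions: int
    seed: int
    fold_errors: np.ndarray      # (repetitions, K) mean NAE per fold
    fold_sizes: np.ndarray       # (repetitions, K)

    @property
    def per_repetition(self) -> np.ndarray:
        """Fold-size-weighted mean NAE of each repetition."""
        return (self.fold_errors * self.fold_sizes).sum(axis=1) / self.fold_sizes.sum(axis=1)

    @property
    def mean(self) -> float:
        return float(self.per_repetition.mean())

    @property
    def sd(self) -> float:
        """Dispersion across repetitions (ddof=1 when possible)."""
        reps = self.per_repetition
        return float(reps.std(ddof=1)) if reps.size > 1 else 0.0

    @property
    def standard_error(self) -> float:
        return self.sd / np.sqrt(self.repetitions)


def normalized_absolute_error(pred: np.ndarray, truth: np.ndarray,
                              signal_range: float) -> float:
    """Mean |pred - truth| / signal_range over all entries."""
    if signal_range <= 0:
        raise ValueError("signal_range must be positive")
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal shapes")
    return float(np.mean(np.abs(pred - truth)) / signal_range)


def choose_K(n_labeled: int, target_per_fold: int = 20) -> int:
    """Pick K so each artificially-unlabeled bin holds about
    ``target_per_fold`` points; clamped to [2, n_labeled]."""
    if n_labeled < 2:
        raise ValueError("need at least 2 labeled points")
    K = round(n_labeled / target_per_fold)
    return int(min(max(K, 2), n_labeled))


def signal_range(Y: np.ndarray) -> float:
    """Range of the signal over the entire labeled set of a channel."""
    return float(np.max(Y) - np.min(Y))


def kfold_cv(W: np.ndarray, labels: ModalityLabels, K: int | None = None,
             repetitions: int = 10, seed: int = 0) -> CVResult:
    """Repeated random K-fold CV of harmonic extension on one modality.

    ``W`` is the affinity over all points (labeled and unlabeled alike).
    Repetition r draws its partition from ``seed + r``, so repetitions
    are reproducible individually.
    """
    lab = labels.labeled_idx
    l = lab.size
    if K is None:
        K = choose_K(l)
    if K < 2 or K > l:
        raise ValueError(f"K={K} incompatible with {l} labeled points")

    Y = labels.Y
    Ymat = Y[:, None] if Y.ndim == 1 else Y
    rng_range = signal_range(Ymat)
    if rng_range == 0:
        rng_range = 1.0  # constant labels: error will be exactly 0 anyway

    fold_err = np.empty((repetitions, K))
    fold_n = np.empty((repetitions, K), dtype=int)
    for r in range(repetitions):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(l)
        bins = np.array_split(perm, K)
        for k, holdout in enumerate(bins):
            if holdout.size == 0:
                raise ValueError("empty CV fold; reduce K")
            keep = np.setdiff1d(np.arange(l), holdout)
            sub = ModalityLabels(labels.name, lab[keep], Ymat[keep])
            traj = harmonic_extension(W, sub)
            vals = traj.values if traj.values.ndim == 2 else traj.values[:, None]
            pred = vals[lab[holdout]]
            fold_err[r, k] = normalized_absolute_error(
                pred, Ymat[holdout], rng_range)
            fold_n[r, k] = holdout.size
    return CVResult(labels.name, K, repetitions, seed, fold_err, fold_n)


def holdout_predictions(W: np.ndarray, labels: ModalityLabels,
                        K: int | None = None, seed: int = 0) -> np.ndarray:
    """Predicted label values for every labeled point, each taken from
    the CV fold in which it was held out (one repetition).

    A held-out point's own label never enters its prediction — only the
    other labels and the graph do.
    """
    lab = labels.labeled_idx
    l = lab.size
    if K is None:
        K = choose_K(l)
    Y = labels.Y
    Ymat = Y[:, None] if Y.ndim == 1 else Y
    preds = np.empty_like(Ymat, dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(l)
    for holdout in np.array_split(perm, K):
        keep = np.setdiff1d(np.arange(l), holdout)
        sub = ModalityLabels(labels.name, lab[keep], Ymat[keep])
        traj = harmonic_extension(W, sub)
        vals = traj.values if traj.values.ndim == 2 else traj.values[:, None]
        preds[holdout] = vals[lab[holdout]]
    return preds if Y.ndim == 2 else preds[:, 0]


def error_vs_unlabeled(x_labeled: np.ndarray, y_labeled: np.ndarray,
                       x_unlabeled: np.ndarray, u_grid: list[int],
                       K: int = 5, repetitions: int = 100, seed: int = 0,
                       k_neighbors: int = 10) -> "pd.DataFrame":
    """CV error as a function of how many unlabeled points join the graph.

    For each u in ``u_grid`` the graph holds all labeled points plus the
    first u unlabeled ones; reports the mean NAE and its Monte-Carlo
    standard error.  Demonstrates the semi-supervised effect: unlabeled
    points densify the manifold and carry information between labeled
    points.
    """
    import pandas as pd

    from .affinity import build_affinity

    if not len(u_grid):
        raise ValueError("u_grid must be non-empty")
    l = x_labeled.shape[0]
    rows = []
    for u in u_grid:
        if u > x_unlabeled.shape[0]:
            raise ValueError(f"u={u} exceeds available unlabeled points")
        X = np.vstack([x_labeled, x_unlabeled[:u]])
        aff = build_affinity(X, k=k_neighbors)
        labels = ModalityLabels("signal", np.arange(l), y_labeled)
        res = kfold_cv(aff.W, labels, K=K, repetitions=repetitions, seed=seed)
        rows.append({"u": u, "mean_nae": res.mean, "sd": res.sd,
                     "se": res.standard_error})
    return pd.DataFrame(rows)
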