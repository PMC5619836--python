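"""Model/Results interface to the fusion core.

:class:`GraphFusionModel` holds the ingredients of one fusion problem —
feature vectors for every observation, the labeled modalities, and the
affinity-graph settings.  ``fit()`` builds the locally-scaled Gaussian
affinity graph and harmonically extends every modality, returning a
:class:`FusionResults` that carries the completed trajectories,
cross-validation diagnostics and a ``summary()`` table.

Typical use::

    study = generate_study(40, [(15, ("dpERK", "Twi")), (15, ("Dl", "rho"))])
    model = GraphFusionModel.from_study(study)
    res = model.fit()
    print(res.summary())
    cv = res.cross_validate(repetitions=10, seed=0)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .affinity import AffinityMatrix, build_affinity
from .features import (FeatureVector, ScatterConfig, center_by_dataset,
                       feature_matrix, scatter_image)
from .harmonic import CompletedTrajectory, ModalityLabels, complete_study
from .validation import CVResult, choose_K, kfold_cv

__all__ = ["GraphFusionModel", "FusionResults"]

TIME_MODALITY = "time"


class GraphFusionModel:
    """Semi-supervised completion of partially observed modalities.

    Parameters
    ----------
    features : (n, d) array or list of FeatureVector
        One feature vector per observation (any representation of the
        common channel — scattering coefficients, raw coordinates, ...).
    modalities : list of ModalityLabels
        The partially observed target variables.
    image_ids : optional list of str
        Observation identifiers (defaults to row numbers).
    metric : "euclidean" or "one-norm"
    n_neighbors : int
        Neighbours used for the local kernel scales (default 10).
    """

    def __init__(self, features, modalities: list[ModalityLabels],
                 image_ids: list[str] | None = None,
                 metric: str = "euclidean", n_neighbors: int = 10):
        if isinstance(features, (list, tuple)) and features and \
                isinstance(features[0], FeatureVector):
            X, ids = feature_matrix(list(features))
            image_ids = image_ids or ids
        else:
            X = np.asarray(features, dtype=float)
        if X.ndim != 2:
            raise ValueError("features must be 2-D")
        if not modalities:
            raise ValueError("no labels for any target modality")
        self.X = X
        self.modalities = list(modalities)
        self.image_ids = list(image_ids) if image_ids else \
            [str(i) for i in range(X.shape[0])]
        self.metric = metric
        self.n_neighbors = n_neighbors
        self._study = None

    # ------------------------------------------------------------------
    @classmethod
    def from_study(cls, study, scatter_cfg: ScatterConfig | None = None,
                   prep_cfg=None, preprocess: bool = True,
                   center: bool = True, include_time: bool = True,
                   metric: str = "euclidean", n_neighbors: int = 10,
                   feature_map=None) -> "GraphFusionModel":
        """Build the model from a study's images.

        The common channel of every image is normalised (register ->
        resize -> renormalize -> logistic) and featurised with the
        scattering transform (or a custom ``feature_map(image) ->
        vector``); feature point clouds are centred per dataset.  Target
        modalities are the molecular channels (per-pixel labels) plus,
        when ``include_time``, the live timestamps.
        """
        from .prep import PrepConfig, prep_pipeline, register

        prep_cfg = prep_cfg or PrepConfig(
            canonical_size=study.image_size if study.image_size < 100 else 100)
        scatter_cfg = scatter_cfg or ScatterConfig(
            averaging_scale=min(64, 2 ** int(np.log2(prep_cfg.canonical_size))))

        feats: list[FeatureVector] = []
        for rec in study.images:
            img = rec.channels[study.common_channel]
            if preprocess:
                img = prep_pipeline(img, rec.ventral_angle, prep_cfg,
                                    dataset_id=rec.dataset_id)
            if feature_map is None:
                fv = scatter_image(img, scatter_cfg,
                                   image_id=rec.image_id, dataset_id=rec.dataset_id)
            else:
                fv = FeatureVector(np.asarray(feature_map(img), dtype=float),
                                   rec.image_id, rec.dataset_id)
            feats.append(fv)
        if center:
            feats = center_by_dataset(feats)
        X, ids = feature_matrix(feats)

        modalities: list[ModalityLabels] = []
        id_to_row = {iid: i for i, iid in enumerate(ids)}
        channels = sorted({c for r in study.images for c in r.channel_names
                           if c != study.common_channel})
        for ch in channels:
            idx, rows = [], []
            for rec in study.images:
                if ch in rec.channels:
                    arr = rec.channels[ch]
                    if rec.ventral_angle:
                        arr = register(arr, rec.ventral_angle,
                                       _mask_source=rec.channels[study.common_channel])
                    idx.append(id_to_row[rec.image_id])
                    rows.append(np.asarray(arr, dtype=float).ravel())
            if idx:
                modalities.append(ModalityLabels(ch, np.array(idx), np.vstack(rows)))
        if include_time:
            idx = [id_to_row[r.image_id] for r in study.images
                   if r.timestamp is not None]
            ts = [r.timestamp for r in study.images if r.timestamp is not None]
            if idx:
                modalities.append(
                    ModalityLabels(TIME_MODALITY, np.array(idx), np.array(ts)))

        model = cls(X, modalities, image_ids=ids, metric=metric,
                    n_neighbors=n_neighbors)
        model._study = study
        return model

    # ------------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def build_affinity(self) -> AffinityMatrix:
        return build_affinity(self.X, k=self.n_neighbors, metric=self.metric)

    def fit(self) -> "FusionResults":
        """Build the graph and harmonically extend every modality."""
        aff = self.build_affinity()
        trajs = complete_study(aff.W, self.modalities)
        return FusionResults(model=self, affinity=aff,
                             trajectories={t.name: t for t in trajs})


@dataclass
class FusionResults:
    """Completed trajectories plus diagnostics for a fitted fusion model."""

    model: GraphFusionModel
    affinity: AffinityMatrix
    trajectories: dict[str, CompletedTrajectory]
    cv_results: dict[str, CVResult] = field(default_factory=dict)

    @property
    def image_ids(self) -> list[str]:
        return self.model.image_ids

    def trajectory(self, name: str) -> CompletedTrajectory:
        return self.trajectories[name]

    @property
    def estimated_times(self) -> pd.Series | None:
        """Timestamps for every observation (observed for live frames,
        harmonically estimated for fixed snapshots)."""
        if TIME_MODALITY not in self.trajectories:
            return None
        t = self.trajectories[TIME_MODALITY]
        return pd.Series(t.values, index=self.image_ids, name=TIME_MODALITY)

    # ------------------------------------------------------------- CV
    def cross_validate(self, K: int | None = None, repetitions: int = 10,
                       seed: int = 0, modalities: list[str] | None = None
                       ) -> pd.DataFrame:
        """Repeated K-fold CV per modality; caches the CVResult objects
        and returns a tidy table (modality, K, repetitions, mean NAE, sd)."""
        names = modalities or list(self.trajectories)
        rows = []
        for m in self.model.modalities:
            if m.name not in names:
                continue
            Km = K if K is not None else choose_K(m.n_labeled)
            res = kfold_cv(self.affinity.W, m, K=Km,
                           repetitions=repetitions, seed=seed)
            self.cv_results[m.name] = res
            rows.append({"modality": m.name, "K": res.K,
                         "repetitions": res.repetitions,
                         "mean_nae": res.mean, "sd": res.sd})
        return pd.DataFrame(rows)

    def diffusion_map(self, n_components: int = 3):
        from .embedding import diffusion_map
        return diffusion_map(self.affinity.W, n_components)

    # --------------------------------------------------------- summary
    def summary(self) -> str:
        m = self.model
        lines = [
            "Graph fusion results",
            "=" * 60,
            f"observations: {m.n_obs}    feature dim: {m.X.shape[1]}",
            f"metric: {m.metric}    local-scale neighbours: {m.n_neighbors}",
            f"affinity: dense {m.n_obs}x{m.n_obs}, sigma in "
            f"[{self.affinity.sigmas.min():.3g}, {self.affinity.sigmas.max():.3g}]",
            "-" * 60,
            f"{'modality':<12}{'labeled':>8}{'estimated':>10}"
            f"{'min':>10}{'max':>10}" + ("{:>12}".format("cv NAE")),
        ]
        for name, traj in self.trajectories.items():
            vals = traj.values
            l = int(traj.labeled_mask.sum())
            cv = self.cv_results.get(name)
            cv_s = f"{cv.mean:.4f}" if cv else "--"
            lines.append(
                f"{name:<12}{l:>8}{vals.shape[0] - l:>10}"
                f"{vals.min():>10.3g}{vals.max():>10.3g}{cv_s:>12}")
        lines.append("=" * 60)
        return "\n".join(lines)
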