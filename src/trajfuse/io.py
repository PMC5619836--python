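"""Reading and writing studies, configs and results on disk.

A study directory holds TIFF/PNG images plus ``manifest.csv`` with one
row per image: image_id, dataset_id, channels (semicolon-separated),
timestamp (blank for fixed snapshots), ventral_angle, files
(semicolon-separated paths, aligned with the channel list).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .prep import PrepConfig
from .features import ScatterConfig
from .records import ImageRecord

__all__ = ["read_image", "load_manifest", "load_config", "save_trajectories",
           "load_trajectories"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image as float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio
        arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.max() > 1.0:
        arr /= 65535.0 if arr.max() > 255 else 255.0
    return arr


def load_manifest(study_dir: str | Path) -> list[ImageRecord]:
    """Read manifest.csv and the images it points to."""
    study_dir = Path(study_dir)
    man = pd.read_csv(study_dir / "manifest.csv")
    required = {"image_id", "dataset_id", "channels", "files"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for _, row in man.iterrows():
        chans = str(row["channels"]).split(";")
        files = str(row["files"]).split(";")
        if len(chans) != len(files):
            raise ValueError(f"{row['image_id']}: channel/file count mismatch")
        ts = row.get("timestamp")
        ts = None if pd.isna(ts) else float(ts)
        va = row.get("ventral_angle", 0.0)
        va = 0.0 if pd.isna(va) else float(va)
        records.append(ImageRecord(
            image_id=str(row["image_id"]), dataset_id=str(row["dataset_id"]),
            channels={c: read_image(study_dir / f) for c, f in zip(chans, files)},
            timestamp=ts, ventral_angle=va,
        ))
    return records


def load_config(path: str | Path | None) -> dict:
    """YAML config -> {'prep': PrepConfig, 'scatter': ScatterConfig, ...}.

    Recognised keys: canonical_size, occupancy, renorm_sigma,
    logistic_gain / logistic_midpoint (mappings keyed by dataset_id),
    averaging_scale, order, n_orientations, n_neighbors, metric,
    common_channel.
    """
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    prep = PrepConfig(
        canonical_size=raw.get("canonical_size", 100),
        occupancy=raw.get("occupancy", 0.8),
        renorm_sigma=raw.get("renorm_sigma", 10.0),
        logistic_gain=raw.get("logistic_gain", {}) or {},
        logistic_midpoint=raw.get("logistic_midpoint", {}) or {},
    )
    scatter = ScatterConfig(
        averaging_scale=raw.get("averaging_scale", 64),
        order=raw.get("order", 2),
        n_orientations=raw.get("n_orientations", 8),
    )
    return {
        "prep": prep,
        "scatter": scatter,
        "n_neighbors": raw.get("n_neighbors", 10),
        "metric": raw.get("metric", "euclidean"),
        "common_channel": raw.get("common_channel", "nuclei"),
    }


def save_trajectories(out_dir: str | Path, trajectories: dict) -> Path:
    """Persist completed trajectories as an .npz plus a JSON sidecar of
    shapes and label provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays, sidecar = {}, {}
    for name, traj in trajectories.items():
        arrays[f"{name}__values"] = traj.values
        arrays[f"{name}__labeled_idx"] = traj.labeled_idx
        sidecar[name] = {"shape": list(traj.values.shape),
                         "n_labeled": int(traj.labeled_idx.size)}
    np.savez_compressed(out_dir / "trajectories.npz", **arrays)
    (out_dir / "trajectories.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir / "trajectories.npz"


def load_trajectories(path: str | Path) -> dict:
    from .harmonic import CompletedTrajectory
    data = np.load(path)
    names = {k.split("__")[0] for k in data.files}
    return {
        n: CompletedTrajectory(n, data[f"{n}__values"], data[f"{n}__labeled_idx"])
        for n in names
    }
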