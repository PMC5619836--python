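"""A synthetic embryo-like imaging study.

Emulates a cross-section view of a patterning embryo: a latent
pseudo-time drives both the morphology seen in the common ``nuclei``
channel (an ellipse of nuclear blobs whose ventral side progressively
invaginates) and smooth per-pixel intensities in a handful of molecular
target channels.  "Live" frames carry a timestamp equal to their
pseudo-time; "fixed" snapshots carry a subset of the molecular channels
and no timestamp.  Rendering is a deterministic function of pseudo-time,
so with zero noise two images at equal pseudo-time are pixel-identical,
and every ground-truth signal is Lipschitz in pseudo-time — the
smoothness assumption the harmonic-extension objective relies on holds
by construction.

The generator does not attempt biological realism (no nuclear division
cycles, no intrinsically variable reporters, no 3-D geometry); only the
smooth monotone dependence of image content on the latent time matters
for exercising the fusion pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..records import ImageRecord

__all__ = ["StudyParams", "SyntheticStudy", "generate_study", "write_study",
           "render_frame", "COMMON_CHANNEL", "TARGET_CHANNELS"]

COMMON_CHANNEL = "nuclei"

#: target channels: (angular centre of expression domain, angular width,
#:  temporal profile kind, profile parameter)
#: angles measured counterclockwise from +x; ventral is -pi/2.
_CHANNEL_DOMAINS = {
    "dpERK": (-np.pi / 2, 0.55, "bump", 0.35),
    "Twi":   (-np.pi / 2, 0.35, "ramp", 0.40),
    "Dl":    (-np.pi / 2, 0.80, "decay", 0.60),
    "rho":   (-np.pi / 6, 0.30, "ramp", 0.55),
    "ind":   (np.pi / 6, 0.30, "bump", 0.65),
}
TARGET_CHANNELS = tuple(_CHANNEL_DOMAINS)


@dataclass(frozen=True)
class StudyParams:
    """Geometry and dynamics of the rendered embryo cross-section.

    Lengths are fractions of the image side.  ``invagination_depth`` is
    the maximal inward deflection of the ventral boundary (reached at
    pseudo-time 1); ``n_nuclei`` blobs of width ``nucleus_sigma`` sit on
    the boundary ring.
    """

    rx: float = 0.36
    ry: float = 0.30
    invagination_depth: float = 0.45   # fraction of ry, at t = 1
    invagination_width: float = 0.6    # radians
    n_nuclei: int = 36
    nucleus_sigma: float = 0.018
    ring_thickness: float = 0.055


def _temporal_profile(kind: str, center: float, t: np.ndarray | float) -> np.ndarray | float:
    """Smooth amplitude in [0, 1] as a function of pseudo-time."""
    t = np.asarray(t, dtype=float)
    if kind == "bump":
        return np.exp(-((t - center) ** 2) / (2 * 0.18 ** 2))
    if kind == "ramp":
        return 1.0 / (1.0 + np.exp(-(t - center) / 0.12))
    if kind == "decay":
        return 1.0 / (1.0 + np.exp((t - center) / 0.15))
    raise ValueError(kind)


def _boundary_radius(theta: np.ndarray, t: float, p: StudyParams) -> np.ndarray:
    """Embryo boundary radius r(theta) in unit-side coordinates.

    The deformation rate is bounded away from zero on all of [0, 1]
    (linear invagination, linear aspect change) so every pseudo-time is
    morphologically distinguishable — the monotone dependence the fusion
    method assumes.
    """
    rx = p.rx * (1.0 + 0.06 * t)
    ry = p.ry * (1.0 - 0.06 * t)
    r_ell = (rx * ry) / np.sqrt(
        (ry * np.cos(theta)) ** 2 + (rx * np.sin(theta)) ** 2
    )
    # ventral invagination deepens linearly with pseudo-time
    dtheta = np.angle(np.exp(1j * (theta - (-np.pi / 2))))
    dent = (
        p.invagination_depth * p.ry * t
        * np.exp(-(dtheta ** 2) / (2 * p.invagination_width ** 2))
    )
    return r_ell - dent


def render_frame(
    t: float,
    image_size: int = 100,
    params: StudyParams | None = None,
    channels: tuple[str, ...] = TARGET_CHANNELS,
) -> dict[str, np.ndarray]:
    """Render the common channel and the requested target channels at time t.

    Deterministic: no randomness enters here, so the output is a smooth
    function of ``t`` alone.
    """
    p = params or StudyParams()
    S = image_size
    # pixel-centre coordinates in units of the image side, origin at centre
    ax = (np.arange(S) + 0.5) / S - 0.5
    X, Ygrid = np.meshgrid(ax, -ax[:, None].ravel(), indexing="xy")
    # row-major grid, origin top-left: +y is up, rows increase downward
    R = np.hypot(X, Ygrid)
    Theta = np.arctan2(Ygrid, X)

    out: dict[str, np.ndarray] = {}

    # nuclei: Gaussian blobs on the (deforming) boundary ring
    th_n = -np.pi + (2 * np.pi) * (np.arange(p.n_nuclei) + 0.5) / p.n_nuclei
    r_n = 0.92 * _boundary_radius(th_n, t, p)
    cx, cy = r_n * np.cos(th_n), r_n * np.sin(th_n)
    nuc = np.zeros((S, S))
    for bx, by in zip(cx, cy):
        nuc += np.exp(-((X - bx) ** 2 + (Ygrid - by) ** 2) / (2 * p.nucleus_sigma ** 2))
    out[COMMON_CHANNEL] = np.clip(nuc, 0.0, 1.0)

    # molecular channels: angular expression domains on the ring, with a
    # smooth per-channel temporal amplitude
    r_b = _boundary_radius(Theta, t, p)
    ring = np.exp(-((R - 0.92 * r_b) ** 2) / (2 * p.ring_thickness ** 2))
    for name in channels:
        th0, width, kind, center = _CHANNEL_DOMAINS[name]
        dth = np.angle(np.exp(1j * (Theta - th0)))
        sector = np.exp(-(dth ** 2) / (2 * width ** 2))
        amp = float(_temporal_profile(kind, center, t))
        out[name] = amp * ring * sector
    return out


@dataclass
class SyntheticStudy:
    """Generated images plus the latent truth needed for validation."""

    images: list[ImageRecord]
    ground_truth: dict[str, dict[str, np.ndarray]]   # image_id -> channel -> grid
    pseudo_time: dict[str, float]                    # image_id -> latent t
    common_channel: str = COMMON_CHANNEL
    target_channels: tuple[str, ...] = TARGET_CHANNELS
    image_size: int = 100
    params: StudyParams = field(default_factory=StudyParams)

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for rec in self.images:
            rows.append({
                "image_id": rec.image_id,
                "dataset_id": rec.dataset_id,
                "channels": ";".join(rec.channel_names),
                "timestamp": rec.timestamp,
                "ventral_angle": rec.ventral_angle,
            })
        return pd.DataFrame(rows)

    def labeled_set(self, channel: str) -> list[str]:
        """Omega(m): image ids whose dataset carries the channel."""
        return [r.image_id for r in self.images if channel in r.channels]

    def lipschitz_estimate(self, channel: str, n_grid: int = 21) -> float:
        """Sup-norm Lipschitz constant of the per-pixel signal in pseudo-time.

        Estimated by finite differences of the noiseless renderer on a
        uniform time grid; reported so downstream smoothness assumptions
        can be checked quantitatively.
        """
        ts = np.linspace(0.0, 1.0, n_grid)
        frames = [
            render_frame(t, self.image_size, self.params, (channel,))[channel]
            if channel != self.common_channel
            else render_frame(t, self.image_size, self.params, ())[self.common_channel]
            for t in ts
        ]
        h = ts[1] - ts[0]
        diffs = [np.max(np.abs(frames[i + 1] - frames[i])) / h for i in range(n_grid - 1)]
        return float(1.25 * max(diffs))  # headroom for between-grid curvature


def generate_study(
    n_live_frames: int,
    fixed_design: list[tuple[int, tuple[str, ...]]],
    image_size: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    params: StudyParams | None = None,
    orientation_jitter: float = 0.0,
) -> SyntheticStudy:
    """Generate a multimodal study: one live movie plus fixed datasets.

    Parameters
    ----------
    n_live_frames : int
        Frames of the live movie; their pseudo-times are equispaced on
        [0, 1] and exposed as timestamps.
    fixed_design : list of (n_images, channel_subset)
        One entry per fixed dataset; each carries the listed target
        channels (plus the common channel).  Pseudo-times of fixed
        snapshots are drawn uniformly at random.
    noise_sd : float
        Per-pixel additive Gaussian noise on every stored channel
        (ground truth stays noiseless).
    orientation_jitter : float
        If positive, fixed snapshots are rotated by a random angle of
        this standard deviation (radians) and the manifest's
        ventral_angle records it, exercising registration downstream.
    """
    if n_live_frames < 1 and not fixed_design:
        raise ValueError("empty design: need live frames and/or fixed datasets")
    if not fixed_design and n_live_frames:
        pass  # a bare movie is permitted; fusion will reject it later
    for _, subset in fixed_design:
        for ch in subset:
            if ch not in _CHANNEL_DOMAINS:
                raise ValueError(f"unknown channel {ch!r}; known: {TARGET_CHANNELS}")
    if any(n <= 0 for n, _ in fixed_design):
        raise ValueError("fixed dataset sizes must be positive")

    rng = np.random.default_rng(seed)
    p = params or StudyParams()
    images: list[ImageRecord] = []
    truth: dict[str, dict[str, np.ndarray]] = {}
    times: dict[str, float] = {}

    def _noisy(a: np.ndarray) -> np.ndarray:
        if noise_sd > 0:
            return a + rng.normal(0.0, noise_sd, a.shape)
        return a

    live_t = np.linspace(0.0, 1.0, n_live_frames) if n_live_frames else np.array([])
    for i, t in enumerate(live_t):
        iid = f"live_{i:04d}"
        frames = render_frame(float(t), image_size, p, TARGET_CHANNELS)
        truth[iid] = {c: frames[c] for c in TARGET_CHANNELS}
        times[iid] = float(t)
        images.append(ImageRecord(
            image_id=iid, dataset_id="live",
            channels={COMMON_CHANNEL: _noisy(frames[COMMON_CHANNEL])},
            timestamp=float(t), ventral_angle=0.0,
        ))

    for d, (n_img, subset) in enumerate(fixed_design):
        ts = np.sort(rng.uniform(0.0, 1.0, size=n_img))
        for i, t in enumerate(ts):
            iid = f"fixed{d}_{i:04d}"
            frames = render_frame(float(t), image_size, p, TARGET_CHANNELS)
            truth[iid] = {c: frames[c] for c in TARGET_CHANNELS}
            times[iid] = float(t)
            angle = float(rng.normal(0.0, orientation_jitter)) if orientation_jitter else 0.0
            chans = {COMMON_CHANNEL: frames[COMMON_CHANNEL]}
            chans.update({c: frames[c] for c in subset})
            if angle:
                from ..prep import _rotate_about_center
                chans = {c: _rotate_about_center(a, angle) for c, a in chans.items()}
            chans = {c: _noisy(a) for c, a in chans.items()}
            images.append(ImageRecord(
                image_id=iid, dataset_id=f"fixed{d}",
                channels=chans, timestamp=None, ventral_angle=angle,
            ))

    return SyntheticStudy(
        images=images, ground_truth=truth, pseudo_time=times,
        image_size=image_size, params=p,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write the study to disk: 16-bit TIFFs, a manifest CSV and a
    ground-truth CSV (pseudo-time per image; per-pixel truth is
    regenerable from it via :func:`render_frame`)."""
    import tifffile

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for rec in study.images:
        for ch, arr in rec.channels.items():
            a = np.clip(arr, 0.0, 1.0)
            tifffile.imwrite(
                out / "images" / f"{rec.image_id}__{ch}.tif",
                (a * 65535).astype(np.uint16),
            )
    man = study.manifest.copy()
    man["files"] = [
        ";".join(f"images/{r.image_id}__{c}.tif" for c in r.channel_names)
        for r in study.images
    ]
    man.to_csv(out / "manifest.csv", index=False)
    gt = pd.DataFrame(
        {"image_id": list(study.pseudo_time), "pseudo_time": list(study.pseudo_time.values())}
    )
    gt.to_csv(out / "ground_truth.csv", index=False)
    return out
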