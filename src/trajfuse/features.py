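"""Translation-insensitive image features via a 2-D scattering transform.

The scattering transform alternates wavelet decompositions and pointwise
modulus, then averages spatially:

    S0 x        = x * phi_J
    S1[j,t] x   = |x * psi_{j,t}| * phi_J
    S2[j1,t1,j2,t2] x = ||x * psi_{j1,t1}| * psi_{j2,t2}| * phi_J,  j2 > j1

with Morlet wavelets psi at dyadic scales 2^j (j < J = log2 averaging
scale) and L orientations, and a Gaussian low-pass phi_J at the averaging
scale.  The resulting coefficients are locally invariant to translation
(up to the averaging scale) and stable to small deformations, which is
what makes Euclidean distances between them a usable similarity between
specimen images.  Second-order paths are restricted to j2 > j1: the
modulus of a scale-j1 band carries negligible energy at finer scales.

Filters are Morlet wavelets built directly in the Fourier domain
(envelope sigma = 0.8 * 2^j, centre frequency 3*pi/4 / 2^j, slant 4/L),
periodised over the grid; coefficients are read out on a coarse spatial
grid of stride equal to the averaging scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScatterConfig", "FeatureVector", "scatter_image", "scatter_many",
           "center_by_dataset", "n_scattering_paths", "pixel_features",
           "feature_matrix"]


@dataclass(frozen=True)
class ScatterConfig:
    averaging_scale: int = 64       # pixels; power of two
    order: int = 2
    n_orientations: int = 8

    def __post_init__(self):
        if self.averaging_scale < 2 or (self.averaging_scale & (self.averaging_scale - 1)):
            raise ValueError("averaging_scale must be a power of two >= 2")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")

    @property
    def J(self) -> int:
        return int(np.log2(self.averaging_scale))


@dataclass
class FeatureVector:
    values: np.ndarray
    image_id: str = ""
    dataset_id: str = ""

    @property
    def dim(self) -> int:
        return int(self.values.size)


def n_scattering_paths(J: int, L: int, order: int = 2) -> int:
    """Number of scattering paths: 1 + J*L first-order and, at order 2,
    L^2 * J*(J-1)/2 second-order paths (j1 < j2)."""
    n = 1 + J * L
    if order == 2:
        n += L * L * (J * (J - 1)) // 2
    return n


# ---------------------------------------------------------------- filters

def _fourier_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    w = 2.0 * np.pi * np.fft.fftfreq(n)
    return np.meshgrid(w, w, indexing="ij")


def _morlet_hat(n: int, j: int, theta: float, slant: float) -> np.ndarray:
    """Fourier transform of a Morlet wavelet, periodised on the grid."""
    sigma = 0.8 * 2.0 ** j
    xi = 3.0 * np.pi / 4.0 / 2.0 ** j
    wx, wy = _fourier_grid(n)
    out = np.zeros((n, n))
    kappa = np.exp(-0.5 * sigma ** 2 * xi ** 2)
    for mx in (-1, 0, 1):
        for my in (-1, 0, 1):
            ax, ay = wx + 2 * np.pi * mx, wy + 2 * np.pi * my
            wu = ax * np.cos(theta) + ay * np.sin(theta)
            wv = -ax * np.sin(theta) + ay * np.cos(theta)
            gab = np.exp(-0.5 * (sigma ** 2 * (wu - xi) ** 2
                                 + (sigma / slant) ** 2 * wv ** 2))
            low = np.exp(-0.5 * (sigma ** 2 * wu ** 2
                                 + (sigma / slant) ** 2 * wv ** 2))
            out += gab - kappa * low
    return out


def _gaussian_hat(n: int, J: int) -> np.ndarray:
    sigma = 0.8 * 2.0 ** J
    wx, wy = _fourier_grid(n)
    out = np.zeros((n, n))
    for mx in (-1, 0, 1):
        for my in (-1, 0, 1):
            ax, ay = wx + 2 * np.pi * mx, wy + 2 * np.pi * my
            out += np.exp(-0.5 * sigma ** 2 * (ax ** 2 + ay ** 2))
    return out


_BANK_CACHE: dict[tuple[int, int, int], dict] = {}


def _filter_bank(n: int, J: int, L: int) -> dict:
    key = (n, J, L)
    if key not in _BANK_CACHE:
        psis = {
            (j, l): _morlet_hat(n, j, np.pi * l / L, slant=4.0 / L)
            for j in range(J) for l in range(L)
        }
        phi_hat = _gaussian_hat(n, J)
        # read-out positions: coarse grid of stride ~2^J, cell centres
        n_pos = max(1, int(np.ceil(n / 2 ** J)))
        idx = np.round((np.arange(n_pos) + 0.5) * n / n_pos - 0.5).astype(int)
        phi_spatial = np.real(np.fft.ifft2(phi_hat))
        windows = np.empty((n_pos * n_pos, n * n))
        k = 0
        for r in idx:
            for c in idx:
                windows[k] = np.roll(np.roll(phi_spatial, r, axis=0),
                                     c, axis=1).ravel()
                k += 1
        _BANK_CACHE[key] = {"psis": psis, "phi_hat": phi_hat,
                            "windows": windows, "n_pos": n_pos}
    return _BANK_CACHE[key]


# ------------------------------------------------------------- transform

def scatter_image(image: np.ndarray, cfg: ScatterConfig | None = None,
                  image_id: str = "", dataset_id: str = "") -> FeatureVector:
    """Scattering coefficients of one image, flattened into a vector.

    The vector is ordered [S0, S1 paths, S2 paths], each path contributing
    the coefficients at the retained coarse-grid positions; its dimension
    is ``n_scattering_paths(J, L, order) * n_positions``.
    """
    cfg = cfg or ScatterConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be a square 2-D array")
    n = image.shape[0]
    if cfg.averaging_scale > n:
        raise ValueError(
            f"averaging_scale {cfg.averaging_scale} exceeds image side {n}")
    J, L = cfg.J, cfg.n_orientations
    bank = _filter_bank(n, J, L)
    windows, psis = bank["windows"], bank["psis"]

    coeffs = [windows @ image.ravel()]
    xhat = np.fft.fft2(image)
    u1_hats: dict[tuple[int, int], np.ndarray] = {}
    for j in range(J):
        for l in range(L):
            u1 = np.abs(np.fft.ifft2(xhat * psis[(j, l)]))
            coeffs.append(windows @ u1.ravel())
            if cfg.order == 2 and j < J - 1:
                u1_hats[(j, l)] = np.fft.fft2(u1)
    if cfg.order == 2:
        for j1 in range(J):
            for l1 in range(L):
                for j2 in range(j1 + 1, J):
                    for l2 in range(L):
                        u2 = np.abs(np.fft.ifft2(u1_hats[(j1, l1)] * psis[(j2, l2)]))
                        coeffs.append(windows @ u2.ravel())
    return FeatureVector(np.concatenate(coeffs), image_id, dataset_id)


def scatter_many(images: dict[str, np.ndarray], dataset_ids: dict[str, str],
                 cfg: ScatterConfig | None = None) -> list[FeatureVector]:
    """Featurize a whole study's common-channel images."""
    return [
        scatter_image(img, cfg, image_id=iid, dataset_id=dataset_ids.get(iid, ""))
        for iid, img in images.items()
    ]


def pixel_features(image: np.ndarray, out_size: int = 10,
                   image_id: str = "", dataset_id: str = "") -> FeatureVector:
    """Plug-in alternative feature map: raw block-averaged pixels.

    Deliberately naive; exists to demonstrate that the downstream fusion
    core is feature-agnostic.
    """
    from skimage.transform import resize
    small = resize(np.asarray(image, dtype=float), (out_size, out_size),
                   order=1, anti_aliasing=True, preserve_range=True)
    return FeatureVector(small.ravel(), image_id, dataset_id)


def center_by_dataset(features: list[FeatureVector]) -> list[FeatureVector]:
    """Subtract each dataset's mean vector (the point clouds of the
    individual datasets are centred separately, removing per-dataset
    offsets such as staining batch effects).  Idempotent."""
    by_ds: dict[str, list[int]] = {}
    for i, f in enumerate(features):
        by_ds.setdefault(f.dataset_id, []).append(i)
    out = list(features)
    for ds, idxs in by_ds.items():
        if len(idxs) == 1:
            warnings.warn(f"dataset {ds!r} has a single image; its feature "
                          "vector is centred to zero", RuntimeWarning)
        mean = np.mean([features[i].values for i in idxs], axis=0)
        for i in idxs:
            out[i] = FeatureVector(features[i].values - mean,
                                   features[i].image_id, features[i].dataset_id)
    return out


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, list[str]]:
    """Stack feature vectors into (n, d) with the image-id row index."""
    dims = {f.dim for f in features}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
    X = np.stack([f.values for f in features])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X, [f.image_id for f in features]
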