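"""Image normalisation: registration, canonical resize, local intensity
renormalisation and logistic contrast.

The canonical form used for feature extraction is a ``canonical_size`` x
``canonical_size`` (default 100 x 100) grid in which the specimen is
centred, oriented with its annotated ventral-most point at a fixed
reference direction (pointing down), occupies ~80% of the frame along
its major axis, and has its intensities flattened by dividing each pixel
by a local Gaussian average and squashed through a logistic curve.

Pixel convention: row-major grid, origin top-left; angles are measured
counterclockwise from +x with +y pointing up (so "down" in the displayed
image is -pi/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.transform import rescale, rotate as sk_rotate

__all__ = ["PrepConfig", "BlankImageError", "register", "resize_to_canonical",
           "renormalize_local", "logistic_contrast", "prep_pipeline"]

#: ventral-most point reference direction after registration
REFERENCE_ANGLE = -np.pi / 2


class BlankImageError(RuntimeError):
    """No segmentable foreground in the image."""


@dataclass
class PrepConfig:
    canonical_size: int = 100
    occupancy: float = 0.8
    renorm_sigma: float = 10.0
    # per-dataset logistic parameters; fall back to the defaults below
    logistic_gain: dict[str, float] = field(default_factory=dict)
    logistic_midpoint: dict[str, float] = field(default_factory=dict)
    default_gain: float = 10.0
    default_midpoint: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.occupancy < 1.0):
            raise ValueError("occupancy must be in (0, 1)")
        if self.canonical_size < 16:
            raise ValueError("canonical_size must be >= 16")
        if self.renorm_sigma <= 0:
            raise ValueError("renorm_sigma must be positive")

    def gain_for(self, dataset_id: str) -> float:
        return self.logistic_gain.get(dataset_id, self.default_gain)

    def midpoint_for(self, dataset_id: str) -> float:
        return self.logistic_midpoint.get(dataset_id, self.default_midpoint)


def _foreground_mask(image: np.ndarray) -> np.ndarray:
    """Otsu threshold on a smoothed image; largest connected component.

    Smoothing scale grows with the image so granular foreground (e.g.
    separate nuclei) merges into one specimen-sized component.
    """
    sigma = max(1.5, min(image.shape) / 32.0)
    sm = ndimage.gaussian_filter(image.astype(float), sigma)
    if not np.any(sm > 0) or np.ptp(sm) == 0:
        raise BlankImageError("image has no foreground")
    thr = threshold_otsu(sm)
    mask = sm > thr
    if not mask.any():
        raise BlankImageError("Otsu threshold left no foreground")
    lab = cc_label(mask)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == largest


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    r, c = np.nonzero(mask)
    return float(r.mean()), float(c.mean())


def _rotate_about_center(image: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate counterclockwise (in the +x/+y-up convention) about the grid centre."""
    # skimage rotates counterclockwise in display coords, where the row
    # axis points down; that matches a ccw rotation in our convention.
    return sk_rotate(image.astype(float), np.degrees(angle_rad),
                     resize=False, order=1, mode="constant", cval=0.0,
                     preserve_range=True)


def register(image: np.ndarray, ventral_angle: float = 0.0,
             _mask_source: np.ndarray | None = None) -> np.ndarray:
    """Centre the specimen and rotate its ventral-most point to the
    reference direction (pointing down).

    ``ventral_angle`` is the annotated direction (radians ccw from +x) of
    the ventral-most point in the input.  ``_mask_source`` lets callers
    segment on a different channel (e.g. register a molecular channel
    using the nuclei mask).
    """
    image = np.asarray(image, dtype=float)
    mask = _foreground_mask(image if _mask_source is None else _mask_source)
    r0, c0 = _centroid(mask)
    nr, nc = image.shape
    shifted = ndimage.shift(image, ((nr - 1) / 2 - r0, (nc - 1) / 2 - c0),
                            order=1, mode="constant", cval=0.0)
    delta = ventral_angle - REFERENCE_ANGLE
    if abs(np.angle(np.exp(1j * delta))) < 1e-12:
        return shifted
    return _rotate_about_center(shifted, -delta)


def resize_to_canonical(image: np.ndarray, cfg: PrepConfig | None = None,
                        _mask_source: np.ndarray | None = None) -> np.ndarray:
    """Rescale and crop/pad so the foreground's major diameter fills
    ``occupancy`` of a ``canonical_size`` square."""
    cfg = cfg or PrepConfig()
    image = np.asarray(image, dtype=float)
    mask = _foreground_mask(image if _mask_source is None else _mask_source)
    r, c = np.nonzero(mask)
    if (r.min() == 0 and r.max() == mask.shape[0] - 1
            and c.min() == 0 and c.max() == mask.shape[1] - 1):
        raise BlankImageError("foreground touches all image borders; cannot frame")
    diameter = float(max(r.max() - r.min() + 1, c.max() - c.min() + 1))
    target = cfg.occupancy * cfg.canonical_size
    factor = target / diameter
    scaled = rescale(image, factor, order=1, mode="constant", cval=0.0,
                     preserve_range=True, anti_aliasing=factor < 1)
    msk = rescale(mask.astype(float), factor, order=1, mode="constant",
                  cval=0.0, preserve_range=True, anti_aliasing=factor < 1) > 0.5
    if not msk.any():
        msk = scaled > scaled.max() * 0.1
    r0, c0 = _centroid(msk)
    S = cfg.canonical_size
    out = np.zeros((S, S))
    # paste `scaled` so its foreground centroid sits at the canvas centre
    top = int(round((S - 1) / 2 - r0))
    left = int(round((S - 1) / 2 - c0))
    src_r0, src_c0 = max(0, -top), max(0, -left)
    dst_r0, dst_c0 = max(0, top), max(0, left)
    h = min(scaled.shape[0] - src_r0, S - dst_r0)
    w = min(scaled.shape[1] - src_c0, S - dst_c0)
    if h > 0 and w > 0:
        out[dst_r0:dst_r0 + h, dst_c0:dst_c0 + w] = \
            scaled[src_r0:src_r0 + h, src_c0:src_c0 + w]
    return out


def renormalize_local(image: np.ndarray, renorm_sigma: float = 10.0) -> np.ndarray:
    """Divide each pixel by a local Gaussian average of the image.

    Flattens slow illumination/staining gradients; invariant to global
    intensity scaling.  The denominator is floored at 1e-6 of the image
    maximum so background pixels do not blow up.
    """
    if renorm_sigma <= 0:
        raise ValueError("renorm_sigma must be positive")
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    local = ndimage.gaussian_filter(image, renorm_sigma, mode="nearest")
    floor = 1e-6 * (image.max() if image.max() > 0 else 1.0)
    return image / np.maximum(local, floor)


def logistic_contrast(image: np.ndarray, gain: float = 10.0,
                      midpoint: float = 0.5) -> np.ndarray:
    """Monotone contrast stretch: 1 / (1 + exp(-gain * (x - midpoint)))."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    image = np.asarray(image, dtype=float)
    return 1.0 / (1.0 + np.exp(-gain * (image - midpoint)))


def prep_pipeline(image: np.ndarray, ventral_angle: float = 0.0,
                  cfg: PrepConfig | None = None,
                  dataset_id: str = "", _mask_source: np.ndarray | None = None
                  ) -> np.ndarray:
    """register -> resize -> renormalize -> logistic, with one config.

    Deterministic: identical input and config give bit-identical output.
    """
    cfg = cfg or PrepConfig()
    img = register(image, ventral_angle, _mask_source=_mask_source)
    msk = None
    if _mask_source is not None:
        msk = register(_mask_source, ventral_angle)
    img = resize_to_canonical(img, cfg, _mask_source=msk)
    img = renormalize_local(np.clip(img, 0.0, None), cfg.renorm_sigma)
    return logistic_contrast(img, cfg.gain_for(dataset_id), cfg.midpoint_for(dataset_id))
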