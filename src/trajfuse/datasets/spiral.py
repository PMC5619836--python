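"""The planar spiral: a one-dimensional trajectory with a scalar signal.

Points live on an Archimedean spiral parameterised by a latent time t,

    x1(t) = a * t * (cos(b t) + eps1)
    x2(t) = a * t * (sin(b t) + eps2)
    y(t)  = c * t * exp(-d (t - e)^2)

with Gaussian noise sources eps1, eps2.  The coordinates (x1, x2) play
the role of the morphology common to every observation; y is a target
modality observed only on the labeled subset.  Without noise the latent
time is recoverable as t = sqrt(x1^2 + x2^2) / |a|, so the signal is a
smooth function of the observed coordinates — exactly the regime where
harmonic extension on a neighbourhood graph works.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpiralParams", "SpiralDataset", "generate_spiral", "spiral_signal"]


@dataclass(frozen=True)
class SpiralParams:
    """Constants of the spiral and its signal.

    a : radial growth rate; b : angular frequency (rad per unit t);
    c : signal amplitude; d : signal decay rate (1/t^2); e : signal peak
    location; noise_sd : standard deviation of the coordinate noise;
    t_range : closed sampling interval for t.
    """

    a: float = 1.0
    b: float = 4.0 * np.pi
    c: float = 1.0
    d: float = 50.0
    e: float = 0.5
    noise_sd: float = 0.02
    t_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.d < 0:
            raise ValueError("d must be non-negative")
        if not self.t_range[1] > self.t_range[0]:
            raise ValueError("t_range must be non-degenerate")


def spiral_signal(t: np.ndarray, params: SpiralParams) -> np.ndarray:
    """Ground-truth signal y(t) = c t exp(-d (t-e)^2)."""
    t = np.asarray(t, dtype=float)
    return params.c * t * np.exp(-params.d * (t - params.e) ** 2)


@dataclass
class SpiralDataset:
    """l + u spiral points; exactly l of them carry the signal label."""

    t_values: np.ndarray            # (n,) latent times
    x: np.ndarray                   # (n, 2) observed coordinates
    y: np.ndarray                   # (n,) ground-truth signal (all points)
    labeled_mask: np.ndarray        # (n,) bool, exactly l True
    params: SpiralParams = field(default_factory=SpiralParams)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    @property
    def n_unlabeled(self) -> int:
        return int((~self.labeled_mask).sum())

    @property
    def labeled_idx(self) -> np.ndarray:
        return np.flatnonzero(self.labeled_mask)


def generate_spiral(
    n_labeled: int,
    n_unlabeled: int,
    params: SpiralParams | None = None,
    seed: int = 0,
    sampling: str = "uniform",
) -> SpiralDataset:
    """Sample a spiral dataset.

    Latent times are drawn i.i.d. uniformly on ``t_range`` (or equispaced
    with ``sampling="equispaced"``); the labeled subset is chosen
    uniformly at random without replacement.  Labeled points expose
    (x, y); unlabeled points expose (x, t) — their ground-truth y is
    retained for validation only.
    """
    if n_labeled < 1:
        raise ValueError("n_labeled must be >= 1")
    if n_unlabeled < 0:
        raise ValueError("n_unlabeled must be >= 0")
    params = params or SpiralParams()
    rng = np.random.default_rng(seed)
    n = n_labeled + n_unlabeled

    lo, hi = params.t_range
    if sampling == "uniform":
        t = rng.uniform(lo, hi, size=n)
    elif sampling == "equispaced":
        t = np.linspace(lo, hi, n)
    else:
        raise ValueError(f"unknown sampling {sampling!r}")
    t = np.sort(t)

    eps1 = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd else np.zeros(n)
    eps2 = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd else np.zeros(n)
    x1 = params.a * t * (np.cos(params.b * t) + eps1)
    x2 = params.a * t * (np.sin(params.b * t) + eps2)
    y = spiral_signal(t, params)

    labeled = np.zeros(n, dtype=bool)
    labeled[rng.choice(n, size=n_labeled, replace=False)] = True

    return SpiralDataset(
        t_values=t, x=np.column_stack([x1, x2]), y=y,
        labeled_mask=labeled, params=params,
    )
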