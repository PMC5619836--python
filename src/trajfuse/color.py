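"""Movie coloring: overlay estimated molecular channels on live frames.

Each channel's estimated per-pixel values are rescaled to [0, 1] by the
range of its training labels, tinted with the channel's display colour
and additively blended over the grayscale common channel, with clipping
to the valid range.  The elapsed time (minutes) is burned into a corner
with a tiny bitmap font so frames remain plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .harmonic import CompletedTrajectory

__all__ = ["ColorScheme", "colorize_frames", "blend_channels"]

#: display colours: dpERK red, Dl pink, rho yellow, ind blue, Twi green
DEFAULT_COLORS = {
    "dpERK": (1.0, 0.0, 0.0),
    "Dl": (1.0, 0.45, 0.70),
    "rho": (1.0, 1.0, 0.0),
    "ind": (0.0, 0.35, 1.0),
    "Twi": (0.0, 0.85, 0.0),
}

_DIGITS = {  # 3x5 bitmap glyphs
    "0": "111101101101111", "1": "010110010010111", "2": "111001111100111",
    "3": "111001111001111", "4": "101101111001001", "5": "111100111001111",
    "6": "111100111101111", "7": "111001001001001", "8": "111101111101111",
    "9": "111101111001111", ".": "000000000000010", " ": "000000000000000",
}


@dataclass
class ColorScheme:
    colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self):
        vals = list(self.colors.values())
        if len({tuple(v) for v in vals}) != len(vals):
            raise ValueError("display colours must be distinct")

    def __getitem__(self, channel: str) -> tuple[float, float, float]:
        return self.colors[channel]


def _burn_text(rgb: np.ndarray, text: str, scale: int = 2) -> None:
    r, c = 2, 2
    for ch in text:
        glyph = _DIGITS.get(ch, _DIGITS[" "])
        for i in range(5):
            for j in range(3):
                if glyph[i * 3 + j] == "1":
                    rgb[r + i * scale:r + (i + 1) * scale,
                        c + j * scale:c + (j + 1) * scale] = 1.0
        c += 4 * scale


def blend_channels(gray: np.ndarray, channel_values: dict[str, np.ndarray],
                   scheme: ColorScheme,
                   ranges: dict[str, tuple[float, float]]) -> np.ndarray:
    """One frame: grayscale base plus additive colour tints, clipped."""
    g = np.clip(np.asarray(gray, dtype=float), 0.0, 1.0)
    rgb = np.stack([g, g, g], axis=-1)
    for name, vals in channel_values.items():
        if name not in scheme.colors:
            raise ValueError(f"no display colour for channel {name!r}")
        lo, hi = ranges[name]
        span = hi - lo if hi > lo else 1.0
        norm = np.clip((np.asarray(vals, dtype=float) - lo) / span, 0.0, 1.0)
        rgb += norm[..., None] * np.asarray(scheme[name])
    return np.clip(rgb, 0.0, 1.0)


def colorize_frames(
    live_frames: list[tuple[float, np.ndarray]],
    trajectories: dict[str, CompletedTrajectory],
    frame_rows: list[int],
    scheme: ColorScheme | None = None,
    frame_step: int = 1,
    minutes_per_unit: float = 1.0,
    label_ranges: dict[str, tuple[float, float]] | None = None,
) -> list[tuple[float, np.ndarray]]:
    """Colour a live movie with the estimated molecular channels.

    Parameters
    ----------
    live_frames : list of (timestamp, grayscale image), time-ordered
    trajectories : completed per-pixel trajectories, one per channel
    frame_rows : row index of each live frame in the trajectory matrices
    frame_step : keep every ``frame_step``-th frame (temporal subsampling)
    minutes_per_unit : converts timestamps to minutes for the burned-in stamp
    label_ranges : per-channel (min, max) used to rescale estimates;
        defaults to the range of each trajectory's training labels
    """
    if frame_step < 1:
        raise ValueError("frame_step must be >= 1")
    scheme = scheme or ColorScheme()
    for name in trajectories:
        if name == "time":
            continue
        if name not in scheme.colors:
            raise ValueError(f"trajectory {name!r} missing from colour scheme")
    channels = [n for n in trajectories if n != "time"]
    if label_ranges is None:
        label_ranges = {}
        for n in channels:
            t = trajectories[n]
            lab_vals = t.values[t.labeled_mask]
            label_ranges[n] = (float(lab_vals.min()), float(lab_vals.max()))

    out = []
    for k in range(0, len(live_frames), frame_step):
        ts, gray = live_frames[k]
        shape = np.asarray(gray).shape
        ch_vals = {
            n: trajectories[n].values[frame_rows[k]].reshape(shape)
            for n in channels
        }
        rgb = blend_channels(gray, ch_vals, scheme, label_ranges)
        _burn_text(rgb, f"{ts * minutes_per_unit:.1f}")
        out.append((ts, rgb))
    return out
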