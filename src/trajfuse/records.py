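"""Shared record types for images and their metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageRecord"]


@dataclass
class ImageRecord:
    """One observation: pixel grids for the channels it carries.

    ``channels`` maps channel name -> 2-D float array.  ``timestamp`` is
    set for live-movie frames and ``None`` for fixed snapshots;
    ``ventral_angle`` is the annotated orientation of the ventral-most
    point (radians, counterclockwise from +x).
    """

    image_id: str
    dataset_id: str
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    timestamp: float | None = None
    ventral_angle: float = 0.0

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __repr__(self) -> str:  # keep the pixel payload out of reprs
        return (
            f"ImageRecord(image_id={self.image_id!r}, dataset_id={self.dataset_id!r}, "
            f"channels={list(self.channels)}, timestamp={self.timestamp}, "
            f"ventral_angle={self.ventral_angle:.3f})"
        )
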