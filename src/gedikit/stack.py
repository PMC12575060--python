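"""Multi-channel, multi-timepoint image container with TIFF round-tripping.

An :class:`ImageStack` holds a ``T x C x H x W`` nonnegative intensity array
together with channel names and acquisition times in hours.  Pixel
coordinates are 0-based ``(row, col)`` with the origin at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A ``T x C x H x W`` fluorescence (or brightfield) image stack.

    Parameters
    ----------
    pixels
        Nonnegative intensities, arbitrary units, shape ``(T, C, H, W)``.
    channel_names
        One name per channel, e.g. ``["red", "green"]``.
    timepoints_h
        Acquisition times in hours, strictly increasing, one per frame.
    """

    pixels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    timepoints_h: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be 4-D (T, C, H, W), got shape {self.pixels.shape}"
            )
        t, c = self.pixels.shape[:2]
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if len(self.timepoints_h) != t:
            raise ValueError(
                f"{len(self.timepoints_h)} timepoints for {t} frames"
            )
        tp = np.asarray(self.timepoints_h, dtype=float)
        if t > 1 and not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints_h must be strictly increasing")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_timepoints(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def frame(self, t: int, channel: str) -> np.ndarray:
        """Return the 2-D image at frame index ``t`` for a named channel."""
        return self.pixels[t, self.channel_index(channel)]

    # -- I/O -------------------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF, pages ordered T-major then C.

        A JSON sidecar ``<path>.json`` records channel names and timepoints
        so the stack round-trips losslessly.
        """
        path = Path(path)
        t, c, h, w = self.pixels.shape
        pages = self.pixels.reshape(t * c, h, w).astype(np.float32)
        tifffile.imwrite(path, pages)
        sidecar = {
            "channel_names": list(self.channel_names),
            "timepoints_h": [float(x) for x in self.timepoints_h],
            "shape": [int(t), int(c), int(h), int(w)],
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ImageStack":
        """Read a stack written by :meth:`to_tiff` (sidecar required)."""
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        pages = tifffile.imread(path)
        t, c, h, w = sidecar["shape"]
        pixels = np.asarray(pages, dtype=float).reshape(t, c, h, w)
        return cls(
            pixels=pixels,
            channel_names=list(sidecar["channel_names"]),
            timepoints_h=list(sidecar["timepoints_h"]),
        )
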