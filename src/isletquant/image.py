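"""Calibrated multi-channel image container and TIFF round-trip.

All quantification operates on :class:`MultiChannelImage`, a stack of
same-shaped 2D intensity planes with an ordered channel list and a pixel
calibration in micrometres per pixel.  Calibration is always carried with
the data and read back from file metadata — downstream code never assumes
a pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MultiChannelImage"]


@dataclass
class MultiChannelImage:
    """A calibrated stack of 2D intensity planes.

    Parameters
    ----------
    planes
        Array of shape ``(n_channels, height, width)``; intensities >= 0.
    channel_names
        Ordered channel labels, one per plane (by convention the nuclear
        counterstain comes first).
    pixel_size_um
        Lateral calibration in micrometres per pixel (> 0).
    bit_depth
        Declared acquisition bit depth; the full-scale intensity is
        ``2**bit_depth - 1``.
    """

    planes: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3:
            raise ValueError("planes must have shape (n_channels, height, width)")
        if len(self.channel_names) != self.planes.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.planes.shape[0]} planes"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.planes.size and self.planes.min() < 0:
            raise ValueError("intensities must be >= 0")

    # -- basic accessors ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.planes.shape[1:]

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def plane(self, name: str) -> np.ndarray:
        return self.planes[self.channel_index(name)]

    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def with_planes(self, planes: np.ndarray) -> "MultiChannelImage":
        return replace(self, planes=planes)

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write as a multi-page TIFF with channel/calibration metadata."""
        arr = self.planes
        if self.bit_depth <= 16:
            arr = np.round(arr).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            arr,
            photometric="minisblack",
            metadata={
                "axes": "CYX",
                "channel_names": list(self.channel_names),
                "pixel_size_um": float(self.pixel_size_um),
                "bit_depth": int(self.bit_depth),
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "MultiChannelImage":
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            meta = (tif.shaped_metadata or [{}])[0]
        if arr.ndim == 2:
            arr = arr[None]
        names = list(meta.get("channel_names", [f"ch{i}" for i in range(arr.shape[0])]))
        return cls(
            planes=arr.astype(np.float64),
            channel_names=names,
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            bit_depth=int(meta.get("bit_depth", 16)),
        )
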