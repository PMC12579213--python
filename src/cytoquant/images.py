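"""Calibrated image containers.

An :class:`ImagePlane` is a single-channel 2D intensity grid with physical
pixel size; an :class:`ImageStack` is a time series of planes with a fixed
frame interval. Intensities are arbitrary fluorescence units and must be
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImagePlane:
    """Single 2D fluorescence image with calibration metadata.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Non-negative intensities (arbitrary units).
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    channel : str
        Channel label (e.g. ``"CFP"``, ``"RFP"``).
    t : float, optional
        Acquisition time in seconds.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    channel: str = ""
    t: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2D array with dims >= 1x1")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def total_intensity(self) -> float:
        return float(self.pixels.sum())

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.pixels.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float = 1.0, channel: str = "") -> "ImagePlane":
        return cls(tifffile.imread(path), pixel_size_um=pixel_size_um, channel=channel)


@dataclass
class ImageStack:
    """Time series of 2D frames sharing calibration.

    ``frames`` has shape (T, rows, cols); ``frame_interval_s`` is the time
    between consecutive frames.
    """

    frames: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (T, rows, cols) array")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("calibration values must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def plane(self, t: int) -> ImagePlane:
        return ImagePlane(
            self.frames[t],
            pixel_size_um=self.pixel_size_um,
            channel=self.channel,
            t=t * self.frame_interval_s,
        )

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float = 1.0,
                  frame_interval_s: float = 1.0, channel: str = "") -> "ImageStack":
        return cls(tifffile.imread(path), pixel_size_um=pixel_size_um,
                   frame_interval_s=frame_interval_s, channel=channel)
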