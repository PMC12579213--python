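"""Actin stress-fiber detection and axial orientation statistics.

Fiber-like objects are segmented by median + Gaussian filtering and
intensity-based binarization, then filtered to components with area between
10 and 150 pixels and second-moment aspect ratio above 5. Orientations are
axial angles in [0, 180) (a fiber has no head or tail), so the mean
orientation and the average angle deviation use the double-angle transform
of axial statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from .images import ImagePlane

AREA_BAND_PX = (10, 150)
MIN_ASPECT_RATIO = 5.0


class UndefinedValueError(ValueError):
    pass


@dataclass
class FiberObject:
    pixels: np.ndarray  # (n, 2) row/col
    area_px: int
    aspect_ratio: float
    orientation_deg: float  # axial, [0, 180)
    centroid: tuple[float, float]


@dataclass
class FiberStats:
    n_fibers: int
    axial_mean_deg: float
    angle_deviation_deg: float


def _axial_orientation_deg(mask_region: np.ndarray) -> float:
    """Axial angle of a binary region in math coords (x=col, y up), [0, 180).

    Derived from central second moments: theta = 0.5 atan2(2 mu11, mu20 -
    mu02) with y = -row.
    """
    rr, cc = np.nonzero(mask_region)
    x = cc - cc.mean()
    y = -(rr - rr.mean())
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    return float(np.degrees(theta) % 180.0)


def detect_fibers(plane: ImagePlane, median_radius_px: int = 1,
                  gaussian_sigma_px: float = 1.0, threshold_policy="otsu",
                  area_band_px: tuple[int, int] = AREA_BAND_PX,
                  min_aspect_ratio: float = MIN_ASPECT_RATIO) -> list[FiberObject]:
    """Detect fiber-like objects and measure their axial orientations.

    Median filter, Gaussian smoothing, threshold (Otsu by default), 8-connected
    labelling, then keep components with ``area_band_px[0] <= area <=
    area_band_px[1]`` and aspect ratio (second-moment ellipse major/minor)
    strictly above ``min_aspect_ratio``. An empty result is allowed.
    """
    px = plane.pixels
    if median_radius_px > 0:
        px = ndimage.median_filter(px, footprint=morphology.disk(median_radius_px))
    if gaussian_sigma_px > 0:
        px = ndimage.gaussian_filter(px, gaussian_sigma_px)
    from .condensates import _resolve_threshold

    thr = _resolve_threshold(px, threshold_policy)
    binary = px > thr
    labels = measure.label(binary, connectivity=2)
    out: list[FiberObject] = []
    for region in measure.regionprops(labels):
        if not area_band_px[0] <= region.area <= area_band_px[1]:
            continue
        minor = max(region.axis_minor_length, 1e-9)
        ar = region.axis_major_length / minor
        if ar <= min_aspect_ratio:
            continue
        sub = np.zeros(labels.shape, dtype=bool)
        sub[tuple(region.coords.T)] = True
        out.append(FiberObject(
            pixels=region.coords,
            area_px=int(region.area),
            aspect_ratio=float(ar),
            orientation_deg=_axial_orientation_deg(sub),
            centroid=tuple(region.centroid),
        ))
    return out


def axial_mean_deg(angles_deg) -> float:
    """Mean axial angle via the double-angle transform, in [0, 180)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float) * 2.0)
    mean = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    return float((np.degrees(mean) / 2.0) % 180.0)


def _acute_axial_diff(a_deg, b_deg):
    d = np.abs(np.asarray(a_deg, dtype=float) - b_deg) % 180.0
    return np.minimum(d, 180.0 - d)


def angle_deviation(objects, reference_deg: float | None = None) -> FiberStats:
    """Average stress-fiber angle deviation.

    Accepts :class:`FiberObject` instances or raw angles. The deviation is
    the mean absolute acute axial difference between each fiber and the
    reference axis — by default the axial (double-angle) mean of the input,
    optionally a supplied axis such as the cell's polarity axis.
    """
    angles = np.array([
        o.orientation_deg if isinstance(o, FiberObject) else float(o)
        for o in objects
    ])
    if angles.size == 0:
        raise UndefinedValueError("angle deviation undefined for zero fibers")
    ref = axial_mean_deg(angles) if reference_deg is None else reference_deg % 180.0
    dev = _acute_axial_diff(angles, ref).mean()
    return FiberStats(n_fibers=len(angles), axial_mean_deg=float(ref),
                      angle_deviation_deg=float(dev))


def orientation_colormap(objects: list[FiberObject], shape) -> np.ndarray:
    """Image whose foreground pixels carry their object's axial angle (deg);
    background is NaN. Render with an hsv colormap over 0-180 degrees."""
    out = np.full(tuple(shape), np.nan)
    for o in objects:
        out[tuple(o.pixels.T)] = o.orientation_deg
    return out


def fibers_to_frame(objects: list[FiberObject]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(id=i, area_px=o.area_px, aspect_ratio=o.aspect_ratio,
             orientation_deg=o.orientation_deg,
             centroid_row=o.centroid[0], centroid_col=o.centroid[1])
        for i, o in enumerate(objects)
    ])
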