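"""Cell-boundary geometry and localization analysis.

Implements the image pipeline used to relate protein localization to cell
migration: median-filter segmentation thresholded at the mean of non-zero
pixels, morphological boundary smoothing, largest-component selection;
Moore-neighbor boundary tracing; per-pixel inward normals from local
quadratic fits; membrane regions five pixels deep along the normals;
ratiometric (e.g. GFP / iRFP) images; the protrusive wedge (+/-45 degrees
around the movement direction) partitioned by fractional distance from the
cell surface to the centroid into leading edge (0-10%), arc area (10-50%)
and center (50-100%); 60 equal boundary windows with per-window mean
intensity and signed edge velocity; kymographs; and shape descriptors
(area, perimeter, second-moment aspect ratio, circularity).

Coordinate conventions: images are indexed (row, col); vector quantities
such as movement directions use math coordinates (x, y) = (col, -row), i.e.
y points up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .images import ImagePlane, ImageStack
from .trajectories import Trajectory


class SegmentationError(RuntimeError):
    pass


@dataclass
class CellMask:
    """Single-cell binary segmentation."""

    mask: np.ndarray  # bool (rows, cols)
    centroid: tuple[float, float]  # (row, col)
    area_px: int

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "CellMask":
        mask = np.asarray(mask, dtype=bool)
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            raise SegmentationError("empty mask")
        return cls(mask=mask, centroid=(float(rr.mean()), float(cc.mean())),
                   area_px=int(mask.sum()))


@dataclass
class BoundaryContour:
    """Closed, ordered (counterclockwise in math coords) boundary pixel loop.

    ``normals`` holds per-pixel inward unit normals (row, col components)
    once :func:`boundary_normals` has been applied.
    """

    pixels: np.ndarray  # (N, 2) int row/col, ordered, closed loop
    normals: np.ndarray | None = None
    flagged: np.ndarray | None = None  # normals that fell back to chord/centroid

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class RegionPartition:
    """Protrusive wedge split into leading edge / arc area / center."""

    wedge: np.ndarray  # bool image
    leading_edge: np.ndarray
    arc_area: np.ndarray
    center: np.ndarray
    direction: tuple[float, float]
    flagged: bool = False  # True when rays crossed a non-star-shaped boundary

    def region(self, name: str) -> np.ndarray:
        return {"leading_edge": self.leading_edge, "arc_area": self.arc_area,
                "center": self.center, "wedge": self.wedge}[name]


@dataclass
class BoundaryWindows:
    """n contiguous near-equal arcs of a boundary contour."""

    contour: BoundaryContour  # rolled so index 0 is the anchor pixel
    window_index: list[np.ndarray]  # per-window indices into contour.pixels

    @property
    def n_windows(self) -> int:
        return len(self.window_index)

    def window_pixels(self, w: int) -> np.ndarray:
        return self.contour.pixels[self.window_index[w]]


@dataclass
class ShapeDescriptors:
    area_um2: float
    perimeter_um: float
    aspect_ratio: float
    circularity: float


# ---------------------------------------------------------------------------
# segmentation


def segment_cell(plane: ImagePlane, median_radius_px: int = 2,
                 smooth_radius_px: int = 2) -> CellMask:
    """Segment the (single, largest) cell in a fluorescence image.

    Median filter -> threshold at the mean intensity of strictly positive
    filtered pixels -> morphological closing (dilation then erosion) to
    smooth the boundary -> keep the largest 8-connected component and fill
    holes.
    """
    px = plane.pixels
    if not np.any(px > 0):
        raise SegmentationError("image has no nonzero pixels")
    filt = ndimage.median_filter(px, footprint=morphology.disk(median_radius_px))
    pos = filt[filt > 0]
    if pos.size == 0:
        raise SegmentationError("filtered image has no positive pixels")
    thr = pos.mean()
    binary = filt >= thr
    if smooth_radius_px > 0:
        binary = morphology.closing(binary, morphology.disk(smooth_radius_px))
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("no foreground after threshold")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return CellMask.from_array(mask)


# ---------------------------------------------------------------------------
# boundary tracing (Moore neighborhood)

# clockwise in (row, col) image coordinates, starting west
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_MOORE_IDX = {off: i for i, off in enumerate(_MOORE)}


def trace_boundary(cell: CellMask) -> BoundaryContour:
    """Ordered closed boundary of the mask by Moore-neighbor tracing.

    Returns the boundary pixel loop oriented counterclockwise in math
    coordinates (x=col, y=-row); consecutive pixels are 8-adjacent.
    """
    mask = np.pad(cell.mask, 1)
    rows, cols = np.nonzero(mask)
    # scan order start: topmost, then leftmost foreground pixel
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    contour: list[tuple[int, int]] = []
    p = start
    backtrack = (start[0], start[1] - 1)  # entered from the west (background)
    first_move = None
    max_iter = 8 * int(mask.sum()) + 8
    for _ in range(max_iter):
        idx = _MOORE_IDX[(backtrack[0] - p[0], backtrack[1] - p[1])]
        found = None
        for i in range(1, 9):
            off = _MOORE[(idx + i) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if mask[q]:
                found = q
                break
            backtrack = q  # last background pixel scanned
        if found is None:  # isolated single pixel
            contour = [start]
            break
        if p == start:
            if first_move is None:
                first_move = found
            elif found == first_move:
                break  # about to repeat the initial move: loop closed
        contour.append(p)
        p = found
    else:
        raise RuntimeError("boundary tracing failed to terminate")

    pts = np.array(contour, dtype=int) - 1  # undo padding
    # orient counterclockwise in math coords (x=col, y=-row)
    x = pts[:, 1].astype(float)
    y = -pts[:, 0].astype(float)
    area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if area2 < 0:
        pts = pts[::-1].copy()
    return BoundaryContour(pixels=pts)


# ---------------------------------------------------------------------------
# normals, membrane region


def boundary_normals(contour: BoundaryContour, cell: CellMask,
                     half_window: int = 2) -> BoundaryContour:
    """Inward unit normals from local quadratic fits.

    For each boundary pixel, a quadratic is fitted to the pixel and
    ``half_window`` neighbors on each side in a chord-aligned local frame
    (the abscissa along the chord between the window endpoints), avoiding the
    vertical-tangent degeneracy of a fixed y=f(x) parameterization. The
    normal is the unit vector perpendicular to the fitted tangent, oriented
    into the mask. Degenerate windows fall back to the chord normal and are
    flagged.
    """
    pts = contour.pixels.astype(float)
    n = len(pts)
    if n < 2 * half_window + 1:
        raise ValueError("contour too short for the requested fit window")
    mask = cell.mask
    normals = np.zeros((n, 2))
    flagged = np.zeros(n, dtype=bool)
    cen = np.array(cell.centroid)
    for i in range(n):
        idx = [(i + j) % n for j in range(-half_window, half_window + 1)]
        win = pts[idx]
        chord = win[-1] - win[0]
        norm_c = np.linalg.norm(chord)
        if norm_c < 1e-9:
            tangent = None
        else:
            u = chord / norm_c
            v = np.array([-u[1], u[0]])
            rel = win - pts[i]
            a = rel @ u
            b = rel @ v
            try:
                coeff = np.polyfit(a, b, 2)
                slope = coeff[1]  # derivative at a=0 (local origin)
                tangent = u + slope * v
                tangent /= np.linalg.norm(tangent)
            except np.linalg.LinAlgError:
                tangent = None
        if tangent is None:
            flagged[i] = True
            to_cen = cen - pts[i]
            nc = np.linalg.norm(to_cen)
            normals[i] = to_cen / nc if nc > 0 else np.array([0.0, 0.0])
            continue
        nvec = np.array([-tangent[1], tangent[0]])
        # orient inward: probe a step along the normal
        inward = None
        for s in (1.5, 2.5):
            q = np.round(pts[i] + s * nvec).astype(int)
            q2 = np.round(pts[i] - s * nvec).astype(int)
            in_q = (0 <= q[0] < mask.shape[0] and 0 <= q[1] < mask.shape[1]
                    and mask[q[0], q[1]])
            in_q2 = (0 <= q2[0] < mask.shape[0] and 0 <= q2[1] < mask.shape[1]
                     and mask[q2[0], q2[1]])
            if in_q and not in_q2:
                inward = nvec
                break
            if in_q2 and not in_q:
                inward = -nvec
                break
        if inward is None:
            # ambiguous probe (thin protrusion): point toward the centroid
            flagged[i] = True
            inward = nvec if np.dot(nvec, cen - pts[i]) >= 0 else -nvec
        normals[i] = inward
    return BoundaryContour(pixels=contour.pixels, normals=normals, flagged=flagged)


def membrane_region(contour: BoundaryContour, cell: CellMask,
                    depth_px: int = 5) -> np.ndarray:
    """Boolean image of the membrane region: each boundary pixel plus
    ``depth_px`` consecutive pixels stepped inward along its normal,
    clipped to the mask."""
    if contour.normals is None:
        raise ValueError("contour has no normals; run boundary_normals first")
    out = np.zeros_like(cell.mask, dtype=bool)
    nr, nc = cell.mask.shape
    for p, nvec in zip(contour.pixels, contour.normals):
        for s in range(depth_px + 1):
            q = np.round(p + s * nvec).astype(int)
            if 0 <= q[0] < nr and 0 <= q[1] < nc and cell.mask[q[0], q[1]]:
                out[q[0], q[1]] = True
    return out


# ---------------------------------------------------------------------------
# ratio image, wedge partition, region intensity


def ratio_image(num: ImagePlane, den: ImagePlane, cell: CellMask,
                floor: float = 1e-9) -> ImagePlane:
    """Pixelwise num/den inside the mask; NaN outside and where the
    denominator is at or below ``floor``."""
    if num.shape != den.shape or num.shape != cell.mask.shape:
        raise ValueError("planes and mask must share dimensions")
    d = den.pixels
    valid = cell.mask & (d > floor)
    if not valid.any():
        raise ValueError("denominator at or below floor everywhere in mask")
    out = np.full(num.shape, np.nan)
    out[valid] = num.pixels[valid] / d[valid]
    return ImagePlane(out, pixel_size_um=num.pixel_size_um,
                      channel=f"{num.channel}/{den.channel}")


def _bearing(rows, cols, centroid):
    """Angle of (pixel - centroid) in math coords (x=col, y=-row)."""
    return np.arctan2(-(rows - centroid[0]), cols - centroid[1])


def _radius_profile(cell: CellMask, n_bins: int = 720):
    """Distance from centroid to the first boundary crossing per bearing bin."""
    cr, cc = cell.centroid
    nr, nc = cell.mask.shape
    max_r = float(np.hypot(nr, nc))
    radii = np.zeros(n_bins)
    thetas = (np.arange(n_bins) + 0.5) / n_bins * 2 * np.pi - np.pi
    step = 0.5
    for i, th in enumerate(thetas):
        dx, dy = np.cos(th), np.sin(th)
        r = 0.0
        last_in = 0.0
        while r < max_r:
            r += step
            pr = int(round(cr - r * dy))
            pc = int(round(cc + r * dx))
            if not (0 <= pr < nr and 0 <= pc < nc) or not cell.mask[pr, pc]:
                break
            last_in = r
        radii[i] = max(last_in, step)
    return thetas, radii


def partition_regions(cell: CellMask, direction, half_angle_deg: float = 45.0,
                      bands=((0.0, 0.1), (0.1, 0.5), (0.5, 1.0))) -> RegionPartition:
    """Partition the protrusive wedge into leading edge / arc area / center.

    The wedge is the set of in-mask pixels whose bearing from the centroid is
    within ``half_angle_deg`` of ``direction`` (an (x, y) vector, y up). Each
    wedge pixel is assigned a band by its fractional distance from the cell
    surface toward the centroid along its ray (0 at the surface, 1 at the
    centroid): [0, 0.1) leading edge, [0.1, 0.5) arc area, [0.5, 1] center.
    For non-star-shaped masks the nearest boundary crossing along the ray is
    used and the partition is flagged.
    """
    direction = np.asarray(direction, dtype=float)
    if np.linalg.norm(direction) == 0:
        raise ValueError("direction must be nonzero")
    dir_angle = np.arctan2(direction[1], direction[0])
    rr, cc = np.nonzero(cell.mask)
    bear = _bearing(rr.astype(float), cc.astype(float), cell.centroid)
    diff = np.angle(np.exp(1j * (bear - dir_angle)))
    in_wedge = np.abs(diff) <= np.deg2rad(half_angle_deg)

    _, radii = _radius_profile(cell)
    n_bins = len(radii)
    bins = ((bear + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    d = np.hypot(rr - cell.centroid[0], cc - cell.centroid[1])
    R = radii[bins]
    frac = (R - d) / R  # 0 at surface, 1 at centroid
    flagged = bool(np.any(d[in_wedge] > R[in_wedge] + 1.0))
    frac = np.clip(frac, 0.0, 1.0)

    shape = cell.mask.shape
    wedge = np.zeros(shape, dtype=bool)
    wedge[rr[in_wedge], cc[in_wedge]] = True
    region_imgs = []
    for lo, hi in bands:
        if hi >= 1.0:
            sel = in_wedge & (frac >= lo)
        else:
            sel = in_wedge & (frac >= lo) & (frac < hi)
        img = np.zeros(shape, dtype=bool)
        img[rr[sel], cc[sel]] = True
        region_imgs.append(img)
    return RegionPartition(wedge=wedge, leading_edge=region_imgs[0],
                           arc_area=region_imgs[1], center=region_imgs[2],
                           direction=(float(direction[0]), float(direction[1])),
                           flagged=flagged)


def region_intensity(ratio: ImagePlane, part: RegionPartition) -> dict[str, float]:
    """Mean of defined (non-NaN) ratio pixels per region; NaN if a region is
    empty or has no defined pixels."""
    out = {}
    for name in ("leading_edge", "arc_area", "center"):
        sel = part.region(name)
        vals = ratio.pixels[sel]
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if vals.size else float("nan")
    return out


# ---------------------------------------------------------------------------
# boundary windows, edge velocity, kymograph, shape


def boundary_windows(contour: BoundaryContour, n: int = 60) -> BoundaryWindows:
    """Split the boundary into ``n`` contiguous arcs of near-equal pixel
    count, anchored at the topmost boundary pixel (smallest row, then
    smallest column) for frame-to-frame comparability."""
    pts = contour.pixels
    if len(pts) < n:
        raise ValueError(f"contour of {len(pts)} px cannot host {n} windows")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    anchor = int(order[0])
    rolled = np.roll(pts, -anchor, axis=0)
    normals = None if contour.normals is None else np.roll(contour.normals,
                                                           -anchor, axis=0)
    idx = np.array_split(np.arange(len(rolled)), n)
    return BoundaryWindows(
        contour=BoundaryContour(pixels=rolled, normals=normals),
        window_index=[np.asarray(w) for w in idx],
    )


def window_intensity(windows: BoundaryWindows, plane: ImagePlane) -> np.ndarray:
    """Per-window mean intensity sampled at the boundary pixels."""
    return np.array([
        plane.pixels[tuple(windows.window_pixels(w).T)].mean()
        for w in range(windows.n_windows)
    ])


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside (Euclidean px units)."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def edge_velocity(mask_t: CellMask, mask_t1: CellMask,
                  windows: BoundaryWindows, dt: float = 1.0,
                  smooth_sigma_px: float = 1.5) -> np.ndarray:
    """Per-window signed boundary velocity between consecutive frames.

    For each window of the frame-t boundary, the mean change in signed
    distance (positive = outward = protrusion, negative = retraction) of its
    pixels between the two masks, divided by ``dt``. The difference field is
    Gaussian-smoothed (``smooth_sigma_px``) before sampling to suppress
    pixel-grid quantization of the distance transform.
    """
    sd0 = _signed_distance(mask_t.mask)
    sd1 = _signed_distance(mask_t1.mask)
    diff = sd1 - sd0
    if smooth_sigma_px > 0:
        diff = ndimage.gaussian_filter(diff, smooth_sigma_px)
    out = np.empty(windows.n_windows)
    for w in range(windows.n_windows):
        px = windows.window_pixels(w)
        out[w] = diff[tuple(px.T)].mean() / dt
    return out


def intensity_velocity_correlation(intensity: np.ndarray,
                                   velocity: np.ndarray) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between per-window/per-frame intensity
    and edge velocity, pooled over all entries."""
    from .condensates import pearson_r

    return pearson_r(np.ravel(intensity), np.ravel(velocity))


def kymograph(stack: ImageStack, path: np.ndarray) -> np.ndarray:
    """(position x time) intensity map sampled along ``path`` (N, 2) pixel
    coordinates for every frame."""
    path = np.asarray(path, dtype=float)
    nr, nc = stack.frames.shape[1:]
    if np.any(path[:, 0] < 0) or np.any(path[:, 0] > nr - 1) or \
            np.any(path[:, 1] < 0) or np.any(path[:, 1] > nc - 1):
        raise IndexError("kymograph path exits the frame")
    out = np.empty((len(path), len(stack)))
    for t in range(len(stack)):
        out[:, t] = ndimage.map_coordinates(stack.frames[t],
                                            [path[:, 0], path[:, 1]], order=1)
    return out


def shape_descriptors(cell: CellMask, pixel_size_um: float = 1.0) -> ShapeDescriptors:
    """Area, perimeter, second-moment-ellipse aspect ratio and circularity
    (4 pi A / P^2)."""
    props = measure.regionprops(cell.mask.astype(int))[0]
    area = props.area * pixel_size_um**2
    perim = props.perimeter * pixel_size_um
    minor = max(props.axis_minor_length, 1e-9)
    return ShapeDescriptors(
        area_um2=float(area),
        perimeter_um=float(perim),
        aspect_ratio=float(props.axis_major_length / minor),
        circularity=float(4 * np.pi * area / perim**2),
    )


# ---------------------------------------------------------------------------
# pipeline helpers


def centroid_trajectory(masks, dt_min: float = 1.0, pixel_size_um: float = 1.0,
                        cell_id: str = "cell") -> Trajectory:
    """Centroid track of a mask movie, in math coords (x=col, y=-row),
    scaled to micrometres."""
    xs, ys = [], []
    for m in masks:
        cm = m if isinstance(m, CellMask) else CellMask.from_array(m)
        ys.append(-cm.centroid[0] * pixel_size_um)
        xs.append(cm.centroid[1] * pixel_size_um)
    t = np.arange(len(xs)) * dt_min
    return Trajectory(t, np.array(xs), np.array(ys), cell_id=cell_id)
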