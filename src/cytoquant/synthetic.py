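"""Synthetic microscopy data with recorded ground truth.

Every generator here emulates one class of input the analysis modules
consume — two-channel condensate cells, per-cell screening populations,
oriented fiber images, persistent random walks, moving cell masks carrying
intensity fields, focal-adhesion puncta, and one-phase-association recovery
curves — and returns, alongside the artifact, a :class:`GroundTruth` record
holding both the nominal parameters and the realized quantities (recountable
directly from the emitted artifact). All randomness flows through a single
``numpy.random.Generator`` seeded explicitly per call, so identical
(parameters, seed) reproduce outputs bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .images import ImagePlane, ImageStack
from .trajectories import Trajectory


class PlacementError(RuntimeError):
    """Objects could not be placed at the requested density/geometry."""


@dataclass
class GroundTruth:
    """Record of what a generator drew.

    ``params`` holds the nominal generator arguments, ``realized`` the
    quantities actually present in the emitted artifact (recountable from it).
    """

    kind: str
    params: dict
    realized: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating, np.bool_)):
                return o.item()
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, default=_default, indent=1)


# ---------------------------------------------------------------------------
# condensate cells


def _place_points(rng, n, shape, min_dist, margin, max_tries=20000):
    """Rejection-sample n points >= min_dist apart, >= margin from edges."""
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if n > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise PlacementError("margin leaves no interior for spot placement")
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} objects with spacing {min_dist} in {shape}"
            )
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist**2 for pr, pc in pts):
            pts.append((r, c))
    return np.array(pts).reshape(n, 2)


def make_condensate_cell(
    n_spots: int,
    spot_sigma_px: float = 2.0,
    spot_amplitude: float = 1000.0,
    background: float = 50.0,
    snr_target: float | None = None,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
):
    """Two-channel image of a cell with co-localized Gaussian condensates.

    Spots are isotropic Gaussians truncated at 4 sigma, placed with centers at
    least 4 sigma apart and away from edges, at identical positions in both
    channels, on a diffuse uniform background. When ``snr_target`` is given
    the background level is solved so that the fraction of integrated
    intensity inside the spot ROIs (disks of radius 4 sigma) equals the
    target; otherwise the supplied ``background`` is used.

    Returns ``(channel_a, channel_b, GroundTruth)``; the ground truth records
    spot centers and the in-ROI intensity fraction recounted from the emitted
    array.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    rng = np.random.default_rng(seed)
    margin = 4.0 * spot_sigma_px + 1
    centers = _place_points(rng, n_spots, shape, 4.0 * spot_sigma_px, margin)

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    signal = np.zeros(shape, dtype=float)
    roi = np.zeros(shape, dtype=bool)
    for r0, c0 in centers:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        inside = d2 <= (4.0 * spot_sigma_px) ** 2
        signal[inside] += spot_amplitude * np.exp(
            -d2[inside] / (2.0 * spot_sigma_px**2)
        )
        roi |= inside

    if snr_target is not None:
        if not 0.0 <= snr_target <= 1.0:
            raise ValueError("snr_target must lie in [0, 1]")
        s = float(signal.sum())
        a_roi = int(roi.sum())
        a_tot = shape[0] * shape[1]
        if n_spots == 0 or snr_target == 0.0:
            bg = background if n_spots == 0 else 0.0
            if n_spots > 0 and snr_target == 0.0:
                raise ValueError("snr_target 0 unreachable with spots present")
        elif snr_target == 1.0:
            bg = 0.0
        else:
            denom = snr_target * a_tot - a_roi
            if denom <= 0:
                raise ValueError(
                    "snr_target below the ROI area fraction is unreachable"
                )
            bg = s * (1.0 - snr_target) / denom
    else:
        bg = background

    img = signal + bg
    plane_a = ImagePlane(img.copy(), channel="CFP")
    plane_b = ImagePlane(img.copy(), channel="RFP")

    tot = float(img.sum())
    realized_fraction = float(img[roi].sum() / tot) if tot > 0 else 0.0
    gt = GroundTruth(
        kind="condensate_cell",
        params=dict(
            n_spots=n_spots,
            spot_sigma_px=spot_sigma_px,
            spot_amplitude=spot_amplitude,
            background=background,
            snr_target=snr_target,
            shape=list(shape),
        ),
        realized=dict(
            centers=centers.tolist(),
            background_level=float(bg),
            in_spot_intensity_fraction=realized_fraction,
            roi_radius_px=4.0 * spot_sigma_px,
        ),
        seed=seed,
    )
    return plane_a, plane_b, gt


# ---------------------------------------------------------------------------
# screening populations


def make_population(
    n_cells: int,
    true_efficiency: float,
    snr_mean: float = 0.5,
    snr_sd: float = 0.1,
    seed: int = 0,
):
    """Per-cell condensate observations for one bait-prey pair.

    Each co-transfected cell is condensate-positive with probability
    ``true_efficiency``; positive cells carry an SNR drawn from a normal
    truncated to [0, 1]. Returns a list of record dicts (cell_id,
    cotransfected, colocalized_positive, snr) plus ground truth with the
    realized positive count.
    """
    if not 0.0 <= true_efficiency <= 1.0:
        raise ValueError("true_efficiency must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    positive = rng.random(n_cells) < true_efficiency
    n_pos = int(positive.sum())
    if snr_sd > 0:
        a = (0.0 - snr_mean) / snr_sd
        b = (1.0 - snr_mean) / snr_sd
        snrs = stats.truncnorm.rvs(a, b, loc=snr_mean, scale=snr_sd,
                                   size=n_pos, random_state=rng)
    else:
        snrs = np.full(n_pos, float(np.clip(snr_mean, 0, 1)))
    records = []
    j = 0
    for i in range(n_cells):
        rec = dict(cell_id=f"cell{i:04d}", cotransfected=True,
                   colocalized_positive=bool(positive[i]), snr=None)
        if positive[i]:
            rec["snr"] = float(snrs[j])
            j += 1
        records.append(rec)
    gt = GroundTruth(
        kind="population",
        params=dict(n_cells=n_cells, true_efficiency=true_efficiency,
                    snr_mean=snr_mean, snr_sd=snr_sd),
        realized=dict(
            positive_count=n_pos,
            efficiency_pct=100.0 * n_pos / n_cells,
            snr_values=[float(s) for s in snrs],
        ),
        seed=seed,
    )
    return records, gt


# ---------------------------------------------------------------------------
# fiber images


def _bar_coverage(shape, center, angle_deg, length_px, width_px):
    """Anti-aliased coverage image of a rectangle (soft 1-px edge)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    theta = np.deg2rad(angle_deg)
    # axis in (x=col, y=-row) math convention
    ux, uy = np.cos(theta), np.sin(theta)
    dx = cc - center[1]
    dy = -(rr - center[0])
    along = dx * ux + dy * uy
    across = -dx * uy + dy * ux
    # coverage ~ product of smooth edge profiles, 0.5 at the nominal edge
    soft = 0.5
    ca = np.clip((length_px / 2 - np.abs(along)) / soft + 0.5, 0, 1)
    cw = np.clip((width_px / 2 - np.abs(across)) / soft + 0.5, 0, 1)
    return ca * cw


def make_fiber_image(
    angles_deg,
    length_px: float = 30.0,
    width_px: float = 3.0,
    intensity: float = 1000.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
):
    """Image of non-overlapping bar-shaped objects at given axial angles.

    Bars are drawn as anti-aliased rectangles and re-binarized (coverage >
    0.5) for the ground-truth mask, whose per-object pixel count, aspect
    ratio (second-moment ellipse) and orientation are recorded.
    """
    from skimage import measure

    angles = list(angles_deg)
    for a in angles:
        if not 0.0 <= a < 180.0:
            raise ValueError("axial angles must lie in [0, 180)")
    rng = np.random.default_rng(seed)
    margin = length_px / 2 + width_px + 2
    min_dist = length_px + width_px + 2  # conservative non-overlap spacing
    centers = _place_points(rng, len(angles), shape, min_dist, margin)

    img = np.zeros(shape, dtype=float)
    objects = []
    for (r0, c0), ang in zip(centers, angles):
        cov = _bar_coverage(shape, (r0, c0), ang, length_px, width_px)
        img += intensity * cov
        mask = cov > 0.5
        props = measure.regionprops(mask.astype(int))[0]
        minor = max(props.axis_minor_length, 1e-9)
        objects.append(
            dict(
                angle_deg=float(ang),
                center=(float(r0), float(c0)),
                pixel_count=int(mask.sum()),
                aspect_ratio=float(props.axis_major_length / minor),
            )
        )
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, shape), 0, None)

    plane = ImagePlane(img, channel="actin")
    gt = GroundTruth(
        kind="fiber_image",
        params=dict(angles_deg=[float(a) for a in angles], length_px=length_px,
                    width_px=width_px, intensity=intensity, noise_sd=noise_sd,
                    shape=list(shape)),
        realized=dict(objects=objects),
        seed=seed,
    )
    return plane, gt


# ---------------------------------------------------------------------------
# trajectories (persistent random walk)


def make_trajectory(
    n_steps: int,
    step_len_um: float = 1.0,
    turn_sd_deg: float = 30.0,
    dt_min: float = 10.0,
    seed: int = 0,
    cell_id: str = "sim",
):
    """Persistent random walk with wrapped-normal turning.

    The heading evolves by normal increments of SD ``turn_sd_deg`` (wrapped
    implicitly by the trigonometry); step length is constant. The
    wrapped-normal increment gives the analytic lag-1 mean step cosine
    exp(-sigma_rad^2 / 2), recorded in the ground truth.
    """
    if n_steps < 7:
        raise ValueError("n_steps must be >= 7 for windowed statistics")
    rng = np.random.default_rng(seed)
    sigma = np.deg2rad(turn_sd_deg)
    heading = np.empty(n_steps)
    heading[0] = rng.uniform(0, 2 * np.pi)
    if n_steps > 1:
        heading[1:] = heading[0] + np.cumsum(rng.normal(0, sigma, n_steps - 1))
    dx = step_len_um * np.cos(heading)
    dy = step_len_um * np.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    t = np.arange(n_steps + 1) * dt_min
    traj = Trajectory(t, x, y, cell_id=cell_id)
    gt = GroundTruth(
        kind="trajectory",
        params=dict(n_steps=n_steps, step_len_um=step_len_um,
                    turn_sd_deg=turn_sd_deg, dt_min=dt_min),
        realized=dict(
            headings_rad=heading.tolist(),
            expected_lag1_cos=float(np.exp(-(sigma**2) / 2.0)),
        ),
        seed=seed,
    )
    return traj, gt


# ---------------------------------------------------------------------------
# moving masks with intensity fields


def make_moving_mask(
    n_frames: int = 10,
    base_radius_px: float = 40.0,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
    protrusion_amp: float = 0.0,
    intensity_fields: dict | None = None,
    shape: tuple[int, int] = (192, 192),
    seed: int = 0,
):
    """Movie of a disk-like cell mask with known centroid path.

    The mask is a disk of ``base_radius_px`` optionally perturbed by a
    low-order radial sinusoid of amplitude ``protrusion_amp`` (fixed random
    phase), drifting by ``drift_px_per_frame`` = (d_col, d_row) each frame.
    ``intensity_fields`` maps channel name -> config dict with keys ``level``
    and optionally ``wedge_direction`` (x, y), ``wedge_half_angle_deg`` and
    ``wedge_factor`` to paint a brighter wedge, or ``rim_factor`` and
    ``rim_depth_frac`` to paint a brighter rim within that fraction of the
    radius from the surface (e.g. a 2x GFP leading edge on a uniform iRFP).

    Returns ``(masks: ndarray (T, R, C) bool, channels: dict name->ImageStack,
    GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    n_lobes = 3
    dx, dy = drift_px_per_frame
    r0 = shape[0] / 2 - (n_frames - 1) * abs(dy) / 2
    c0 = shape[1] / 2 - (n_frames - 1) * abs(dx) / 2
    if dy < 0:
        r0 = shape[0] / 2 + (n_frames - 1) * abs(dy) / 2
    if dx < 0:
        c0 = shape[1] / 2 + (n_frames - 1) * abs(dx) / 2

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    masks = np.zeros((n_frames,) + tuple(shape), dtype=bool)
    channels: dict[str, np.ndarray] = {
        name: np.zeros((n_frames,) + tuple(shape), dtype=float)
        for name in (intensity_fields or {})
    }
    centroids = []
    max_r = base_radius_px + abs(protrusion_amp)
    for f in range(n_frames):
        cr = r0 + f * dy
        ccol = c0 + f * dx
        if (cr - max_r < 1 or cr + max_r > shape[0] - 2
                or ccol - max_r < 1 or ccol + max_r > shape[1] - 2):
            raise PlacementError("mask would touch the frame border")
        ang = np.arctan2(-(rr - cr), cc - ccol)
        radius = base_radius_px + protrusion_amp * np.sin(n_lobes * ang + phase)
        d = np.hypot(rr - cr, cc - ccol)
        mask = d <= radius
        masks[f] = mask
        fg = np.flatnonzero(mask)
        crr = rr.ravel()[fg].mean()
        ccc = cc.ravel()[fg].mean()
        centroids.append((float(crr), float(ccc)))
        for name, cfg in (intensity_fields or {}).items():
            img = np.zeros(shape)
            level = cfg.get("level", 100.0)
            img[mask] = level
            rim_factor = cfg.get("rim_factor")
            if rim_factor is not None:
                depth = cfg.get("rim_depth_frac", 0.1) * base_radius_px
                from scipy import ndimage as _ndi

                rim = mask & (_ndi.distance_transform_edt(mask) <= depth)
                img[rim] = level * rim_factor
            wd = cfg.get("wedge_direction")
            if wd is not None:
                half = np.deg2rad(cfg.get("wedge_half_angle_deg", 45.0))
                factor = cfg.get("wedge_factor", 2.0)
                wang = np.arctan2(wd[1], wd[0])
                diff = np.angle(np.exp(1j * (ang - wang)))
                wedge = mask & (np.abs(diff) <= half)
                img[wedge] = level * factor
            channels[name][f] = img

    stacks = {
        name: ImageStack(arr, channel=name) for name, arr in channels.items()
    }
    gt = GroundTruth(
        kind="moving_mask",
        params=dict(n_frames=n_frames, base_radius_px=base_radius_px,
                    drift_px_per_frame=list(drift_px_per_frame),
                    protrusion_amp=protrusion_amp, shape=list(shape),
                    intensity_fields={k: dict(v) for k, v in
                                      (intensity_fields or {}).items()}),
        realized=dict(centroids_rc=centroids, phase=float(phase)),
        seed=seed,
    )
    return masks, stacks, gt


# ---------------------------------------------------------------------------
# adhesion puncta

ADHESION_INTENSITY_BAND = (1200.0, 4500.0)
ADHESION_SIZE_BAND = (0.5, 15.0)  # area in um^2 by default


def make_puncta_image(
    puncta,
    pixel_size_um: float = 0.2,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
):
    """Image of plateau-disk puncta of requested area (um^2) and intensity.

    ``puncta`` is a list of ``(area_um2, peak_intensity)``. Ground truth
    records each punctum's drawn pixel area and whether it satisfies the
    focal-adhesion acceptance band (intensity 1200-4500 a.u., size 0.5-15
    um^2).
    """
    rng = np.random.default_rng(seed)
    puncta = list(puncta)
    radii_px = [np.sqrt(a / np.pi) / pixel_size_um for a, _ in puncta]
    max_r = max(radii_px, default=1.0)
    margin = max_r + 3
    min_dist = 2 * max_r + 4
    centers = _place_points(rng, len(puncta), shape, min_dist, margin)

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, dtype=float)
    entries = []
    for (r0, c0), (area, inten), rad in zip(centers, puncta, radii_px):
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        img[disk] = inten
        drawn_area_um2 = float(disk.sum()) * pixel_size_um**2
        in_band = (
            ADHESION_INTENSITY_BAND[0] <= inten <= ADHESION_INTENSITY_BAND[1]
            and ADHESION_SIZE_BAND[0] <= drawn_area_um2 <= ADHESION_SIZE_BAND[1]
        )
        entries.append(
            dict(center=(float(r0), float(c0)), requested_area_um2=float(area),
                 drawn_area_um2=drawn_area_um2, peak_intensity=float(inten),
                 in_band=bool(in_band))
        )
    plane = ImagePlane(img, pixel_size_um=pixel_size_um, channel="zyxin")
    gt = GroundTruth(
        kind="puncta_image",
        params=dict(puncta=[[float(a), float(i)] for a, i in puncta],
                    pixel_size_um=pixel_size_um, shape=list(shape)),
        realized=dict(puncta=entries,
                      in_band_count=int(sum(e["in_band"] for e in entries))),
        seed=seed,
    )
    return plane, gt


# ---------------------------------------------------------------------------
# FRAP curves


def make_frap_curve(
    f0: float = 0.2,
    plateau: float = 0.8,
    k: float = 0.05,
    t=None,
    noise_sd: float = 0.0,
    pre_bleach_frames: int = 30,
    seed: int = 0,
):
    """One-phase-association recovery curve with pre-bleach baseline at 1.

    Post-bleach values follow F(t') = f0 + (plateau - f0)(1 - exp(-k t'))
    with t' measured from the bleach; Gaussian noise of SD ``noise_sd`` is
    added to every frame. Returns an :class:`cytoquant.kinetics.IntensityCurve`
    and ground truth.
    """
    from .kinetics import IntensityCurve

    if not (0.0 <= f0 <= plateau <= 1.0):
        raise ValueError("require 0 <= f0 <= plateau <= 1")
    if k <= 0:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    if t is None:
        t = np.arange(0.0, 150.0, 1.0)
    t = np.asarray(t, dtype=float)
    # uniform acquisition grid: pre-bleach frames, then the post-bleach grid
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    full_t = np.arange(len(t) + pre_bleach_frames) * dt
    post = f0 + (plateau - f0) * (1.0 - np.exp(-k * t))
    values = np.concatenate([np.ones(pre_bleach_frames), post])
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, len(values))
    curve = IntensityCurve(t=full_t, values=values, pre_frames=pre_bleach_frames)
    gt = GroundTruth(
        kind="frap_curve",
        params=dict(f0=f0, plateau=plateau, k=k, noise_sd=noise_sd,
                    pre_bleach_frames=pre_bleach_frames, n_post=len(t)),
        realized=dict(t_half=float(np.log(2) / k),
                      mobile_fraction=float((plateau - f0) / (1.0 - f0))
                      if f0 < 1 else 0.0),
        seed=seed,
    )
    return curve, gt
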