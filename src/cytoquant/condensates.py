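"""Condensate detection and protein-interaction scoring.

A bait-prey interaction is read out from two-channel images of cells in which
interacting proteins co-assemble into visible condensates. Per pair, three
numbers are computed:

* **efficiency** — percentage of co-transfected cells showing co-localized
  condensates in both channels;
* **SNR** — per positive cell, the fraction of the cell's total integrated
  fluorescence residing inside detected condensates (in [0, 1]);
* **raw protein interaction index** — (efficiency / 100) x mean SNR over the
  positive cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters, measure

from .images import ImagePlane

MIN_PARTICLE_AREA_PX = 4  # suppress single-pixel shot noise


class UndefinedValueError(ValueError):
    """A requested quantity is undefined for the given input."""


@dataclass
class Particle:
    """One detected condensate: pixel coordinates, area, integrated intensity."""

    pixels: np.ndarray  # (n, 2) row/col indices
    area_px: int
    integrated_intensity: float
    centroid: tuple[float, float]


@dataclass
class CondensateSet:
    particles: list[Particle]
    threshold_used: float

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def total_intensity(self) -> float:
        return float(sum(p.integrated_intensity for p in self.particles))

    @property
    def centroids(self) -> np.ndarray:
        if not self.particles:
            return np.empty((0, 2))
        return np.array([p.centroid for p in self.particles])


@dataclass
class CellPPIRecord:
    """Per-cell observation for one bait-prey pair."""

    cell_id: str
    cotransfected: bool
    colocalized_positive: bool
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.snr is not None and not self.colocalized_positive:
            raise ValueError("snr is only defined for condensate-positive cells")
        if self.colocalized_positive and not self.cotransfected:
            raise ValueError("a positive cell must be co-transfected")


@dataclass
class PairScore:
    """Summary of one bait-prey pair across cells."""

    bait: str
    prey: str
    efficiency_pct: float
    snr_mean: float
    pi_raw: float
    n_cells: int


def _resolve_threshold(pixels: np.ndarray, policy) -> float:
    """Resolve a threshold policy: 'auto', 'otsu', 'fixed:V', 'pct:P', or a
    number.

    ``auto`` estimates the diffuse background as the image median plus three
    robust standard deviations (1.4826 x MAD), appropriate when condensates
    occupy a small area fraction; ``otsu`` is the classic bimodal split.
    """
    if isinstance(policy, (int, float)):
        return float(policy)
    if isinstance(policy, str):
        if policy == "auto":
            med = float(np.median(pixels))
            mad = float(np.median(np.abs(pixels - med)))
            return med + 3.0 * 1.4826 * mad
        if policy == "otsu":
            if np.ptp(pixels) == 0:
                return float(pixels.max()) + 1.0  # blank image -> nothing above
            return float(filters.threshold_otsu(pixels))
        if policy.startswith("fixed:"):
            return float(policy.split(":", 1)[1])
        if policy.startswith("pct:"):
            return float(np.percentile(pixels, float(policy.split(":", 1)[1])))
    raise ValueError(f"invalid threshold policy: {policy!r}")


def detect_condensates(plane: ImagePlane, threshold_policy="auto",
                       min_area_px: int = MIN_PARTICLE_AREA_PX) -> CondensateSet:
    """Detect condensates as 8-connected components above a threshold.

    Components smaller than ``min_area_px`` are removed. A blank image under
    the automatic policy yields an empty set.
    """
    px = plane.pixels
    thr = _resolve_threshold(px, threshold_policy)
    binary = px > thr
    labels = measure.label(binary, connectivity=2)
    particles: list[Particle] = []
    for region in measure.regionprops(labels, intensity_image=px):
        if region.area < min_area_px:
            continue
        particles.append(
            Particle(
                pixels=region.coords,
                area_px=int(region.area),
                integrated_intensity=float(px[tuple(region.coords.T)].sum()),
                centroid=tuple(region.centroid),
            )
        )
    return CondensateSet(particles=particles, threshold_used=thr)


def compute_snr(plane: ImagePlane, condensates: CondensateSet) -> float:
    """Condensate SNR: sum of particle integrated intensities over total ROI
    integrated intensity. Lies in [0, 1]."""
    total = plane.total_intensity()
    if total <= 0:
        raise UndefinedValueError("total ROI intensity is zero; SNR undefined")
    return condensates.total_intensity / total


def colocalize(a: CondensateSet, b: CondensateSet, max_dist_px: float = 5.0,
               min_matched: int = 1):
    """Greedy nearest-centroid matching of condensates across two channels.

    Repeatedly matches the globally closest unmatched pair with centroid
    distance <= ``max_dist_px``. Returns ``(matches, positive)`` where
    ``matches`` is a list of (index_a, index_b) and ``positive`` is True when
    at least ``min_matched`` pairs matched.
    """
    ca, cb = a.centroids, b.centroids
    matches: list[tuple[int, int]] = []
    if len(ca) and len(cb):
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        free_a = set(range(len(ca)))
        free_b = set(range(len(cb)))
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if d[i, j] > max_dist_px:
                break
            if i in free_a and j in free_b:
                matches.append((int(i), int(j)))
                free_a.discard(int(i))
                free_b.discard(int(j))
    return matches, len(matches) >= min_matched


def efficiency(records: list[CellPPIRecord]) -> float:
    """Condensate-formation efficiency: 100 x positive / co-transfected cells."""
    n_co = sum(1 for r in records if r.cotransfected)
    if n_co == 0:
        raise UndefinedValueError("no co-transfected cells; efficiency undefined")
    n_pos = sum(1 for r in records if r.cotransfected and r.colocalized_positive)
    return 100.0 * n_pos / n_co


def pair_score(bait: str, prey: str, records: list[CellPPIRecord]) -> PairScore:
    """Score one bait-prey pair: efficiency, mean SNR over positive cells,
    and raw PI = (efficiency / 100) x snr_mean."""
    if not records:
        raise ValueError("records must be nonempty")
    eff = efficiency(records)
    snrs = [r.snr for r in records if r.colocalized_positive and r.snr is not None]
    snr_mean = float(np.mean(snrs)) if snrs else 0.0
    return PairScore(
        bait=bait,
        prey=prey,
        efficiency_pct=eff,
        snr_mean=snr_mean,
        pi_raw=(eff / 100.0) * snr_mean,
        n_cells=len(records),
    )


def line_profile(plane: ImagePlane, p0, p1, n_samples: int = 100) -> np.ndarray:
    """Bilinear intensity profile at ``n_samples`` evenly spaced points
    between image points p0=(row, col) and p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    nr, nc = plane.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= nr - 1 and 0 <= p[1] <= nc - 1):
            raise IndexError(f"profile endpoint {p} outside image {plane.shape}")
    frac = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + frac * (p1[0] - p0[0])
    cols = p0[1] + frac * (p1[1] - p0[1])
    return ndimage.map_coordinates(plane.pixels, [rows, cols], order=1)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-tailed p-value from the
    t transform with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def records_to_frame(records: list[CellPPIRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(cell_id=r.cell_id, cotransfected=r.cotransfected,
              colocalized_positive=r.colocalized_positive, snr=r.snr)
         for r in records]
    )


def records_from_frame(df: pd.DataFrame) -> list[CellPPIRecord]:
    recs = []
    for _, row in df.iterrows():
        snr = row.get("snr")
        if snr is not None and (isinstance(snr, float) and np.isnan(snr)):
            snr = None
        recs.append(CellPPIRecord(str(row["cell_id"]), bool(row["cotransfected"]),
                                  bool(row["colocalized_positive"]), snr))
    return recs
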