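"""Segmentation, boundary tracing, normals, regions, windows, velocity."""

import numpy as np
import pytest
from scipy import ndimage

from cytoquant import geometry as geo
from cytoquant import synthetic as sy
from cytoquant.images import ImagePlane, ImageStack
from cytoquant.motion import windowed_direction

from conftest import make_disk_mask


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


def _euclid_dilate(mask, r):
    """Grow a mask by true Euclidean distance r (not a structuring element)."""
    return mask | (ndimage.distance_transform_edt(~mask) <= r)


class TestSegmentation:
    def test_disk_recovered_with_high_iou(self, disk_mask, disk_plane):
        cell = geo.segment_cell(disk_plane)
        assert _iou(cell.mask, disk_mask) >= 0.99

    def test_largest_of_two_cells_kept(self):
        big = make_disk_mask(radius=30, center=(40, 40))
        small = make_disk_mask(radius=10, center=(100, 100))
        cell = geo.segment_cell(ImagePlane((big | small) * 100.0))
        assert _iou(cell.mask, big) >= 0.99
        assert not (cell.mask & small).any()

    def test_all_zero_image_rejected(self):
        with pytest.raises(geo.SegmentationError):
            geo.segment_cell(ImagePlane(np.zeros((64, 64))))

    def test_idempotent_on_own_output(self, disk_plane):
        cell = geo.segment_cell(disk_plane)
        again = geo.segment_cell(ImagePlane(cell.mask * 100.0))
        assert np.array_equal(cell.mask, again.mask)

    def test_interior_hole_filled(self, disk_mask):
        img = disk_mask * 100.0
        img[62:67, 62:67] = 0.0
        cell = geo.segment_cell(ImagePlane(img))
        assert cell.mask[64, 64]

    def test_noise_robustness(self, disk_mask):
        rng = np.random.default_rng(0)
        img = disk_mask * 100.0 + rng.normal(0, 5, disk_mask.shape)
        cell = geo.segment_cell(ImagePlane(np.clip(img, 0, None)))
        assert _iou(cell.mask, disk_mask) >= 0.97


class TestBoundaryTracing:
    def test_square_boundary_pixel_count(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 10x10 square: 36 boundary pixels
        contour = geo.trace_boundary(geo.CellMask.from_array(mask))
        assert len(contour) == 36

    def test_contour_is_closed_8_connected_loop(self, disk_cell):
        pts = geo.trace_boundary(disk_cell).pixels
        gaps = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
        assert gaps.max() <= 1

    def test_counterclockwise_in_math_coords(self, disk_cell):
        pts = geo.trace_boundary(disk_cell).pixels
        x, y = pts[:, 1].astype(float), -pts[:, 0].astype(float)
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area2 > 0

    def test_circle_path_length_near_circumference(self, disk_cell):
        pts = geo.trace_boundary(disk_cell).pixels.astype(float)
        closed = np.vstack([pts, pts[:1]])
        length = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert length == pytest.approx(2 * np.pi * 40, rel=0.10)

    def test_single_pixel_mask(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        contour = geo.trace_boundary(geo.CellMask.from_array(mask))
        assert len(contour) == 1 and tuple(contour.pixels[0]) == (2, 2)

    def test_every_boundary_pixel_touches_background(self, disk_cell):
        pts = geo.trace_boundary(disk_cell).pixels
        padded = np.pad(disk_cell.mask, 1)
        for r, c in pts:
            neigh = padded[r : r + 3, c : c + 3]
            assert not neigh.all()


class TestNormals:
    def test_disk_normals_point_to_center(self, disk_cell):
        contour = geo.boundary_normals(geo.trace_boundary(disk_cell), disk_cell)
        cen = np.array(disk_cell.centroid)
        errs = []
        for p, nvec in zip(contour.pixels, contour.normals):
            to_cen = cen - p
            to_cen = to_cen / np.linalg.norm(to_cen)
            cosang = np.clip(np.dot(nvec, to_cen), -1, 1)
            errs.append(np.degrees(np.arccos(cosang)))
        assert max(errs) <= 10.0

    def test_normals_are_unit_vectors(self, disk_cell):
        contour = geo.boundary_normals(geo.trace_boundary(disk_cell), disk_cell)
        assert np.allclose(np.linalg.norm(contour.normals, axis=1), 1.0)

    def test_straight_edge_normal_is_perpendicular(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        cell = geo.CellMask.from_array(mask)
        contour = geo.boundary_normals(geo.trace_boundary(cell), cell)
        # pixels well inside the top edge (row 5): inward normal is (1, 0)
        for p, nvec in zip(contour.pixels, contour.normals):
            if p[0] == 5 and 12 <= p[1] <= 28:
                assert np.allclose(nvec, (1.0, 0.0), atol=np.sin(np.deg2rad(10)))

    def test_short_contour_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        cell = geo.CellMask.from_array(mask)
        with pytest.raises(ValueError):
            geo.boundary_normals(geo.trace_boundary(cell), cell)


class TestMembraneRegion:
    def test_region_is_subset_of_mask(self, disk_cell):
        contour = geo.boundary_normals(geo.trace_boundary(disk_cell), disk_cell)
        mem = geo.membrane_region(contour, disk_cell)
        assert not (mem & ~disk_cell.mask).any()

    def test_disk_membrane_matches_annulus(self, disk_cell, disk_mask):
        contour = geo.boundary_normals(geo.trace_boundary(disk_cell), disk_cell)
        mem = geo.membrane_region(contour, disk_cell, depth_px=5)
        # reference annulus: the 6-px-wide rim of the disk
        dist = ndimage.distance_transform_edt(disk_mask)
        annulus = disk_mask & (dist <= 6.0)
        assert _iou(mem, annulus) >= 0.75
        assert not (mem & (dist > 7.0)).any()  # never reaches deeper
        # area about perimeter x depth
        assert mem.sum() == pytest.approx(2 * np.pi * 40 * 5, rel=0.15)

    def test_depth_zero_is_boundary_only(self, disk_cell):
        contour = geo.boundary_normals(geo.trace_boundary(disk_cell), disk_cell)
        mem = geo.membrane_region(contour, disk_cell, depth_px=0)
        bpx = {tuple(p) for p in contour.pixels}
        assert {tuple(p) for p in np.argwhere(mem)} == bpx

    def test_depth_monotone(self, disk_cell):
        contour = geo.boundary_normals(geo.trace_boundary(disk_cell), disk_cell)
        areas = [geo.membrane_region(contour, disk_cell, depth_px=d).sum()
                 for d in (0, 2, 5, 8)]
        assert all(a < b for a, b in zip(areas, areas[1:]))


class TestRatioImage:
    def test_uniform_ratio(self, disk_cell, disk_mask):
        num = ImagePlane(disk_mask * 30.0)
        den = ImagePlane(disk_mask * 10.0)
        ratio = geo.ratio_image(num, den, disk_cell)
        inside = ratio.pixels[disk_mask]
        assert np.allclose(inside, 3.0)
        assert np.isnan(ratio.pixels[~disk_mask]).all()

    def test_zero_denominator_pixels_are_nan(self, disk_cell, disk_mask):
        den_px = disk_mask * 10.0
        den_px[60:68, 60:68] = 0.0
        ratio = geo.ratio_image(ImagePlane(disk_mask * 5.0), ImagePlane(den_px),
                                disk_cell)
        assert np.isnan(ratio.pixels[62, 62])

    def test_all_zero_denominator_rejected(self, disk_cell, disk_mask):
        with pytest.raises(ValueError):
            geo.ratio_image(ImagePlane(disk_mask * 5.0),
                            ImagePlane(np.zeros(disk_mask.shape)), disk_cell)

    def test_shape_mismatch_rejected(self, disk_cell, disk_mask):
        with pytest.raises(ValueError):
            geo.ratio_image(ImagePlane(np.ones((10, 10))),
                            ImagePlane(disk_mask * 1.0), disk_cell)


class TestPartition:
    def test_wedge_covers_quarter_of_disk(self, disk_cell, disk_mask):
        part = geo.partition_regions(disk_cell, direction=(1.0, 0.0))
        frac = part.wedge.sum() / disk_mask.sum()
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_band_fractions_match_disk_geometry(self, disk_cell):
        part = geo.partition_regions(disk_cell, direction=(0.0, 1.0))
        w = part.wedge.sum()
        # for a disk, fraction-from-surface bands [0,0.1)/[0.1,0.5)/[0.5,1]
        # occupy 1-0.9^2 = 0.19, 0.9^2-0.5^2 = 0.56 and 0.5^2 = 0.25 of area
        assert part.leading_edge.sum() / w == pytest.approx(0.19, abs=0.03)
        assert part.arc_area.sum() / w == pytest.approx(0.56, abs=0.03)
        assert part.center.sum() / w == pytest.approx(0.25, abs=0.03)

    def test_regions_disjoint_and_cover_wedge(self, disk_cell):
        part = geo.partition_regions(disk_cell, direction=(1.0, 1.0))
        le, arc, cen = part.leading_edge, part.arc_area, part.center
        assert not (le & arc).any() and not (arc & cen).any() and not (le & cen).any()
        assert np.array_equal(le | arc | cen, part.wedge)

    def test_wedge_rotates_with_direction(self, disk_cell):
        right = geo.partition_regions(disk_cell, direction=(1.0, 0.0))
        up = geo.partition_regions(disk_cell, direction=(0.0, 1.0))
        # up-wedge is the right-wedge rotated 90 degrees: same size,
        # small overlap (only at the shared rays)
        assert up.wedge.sum() == pytest.approx(right.wedge.sum(), rel=0.03)
        overlap = (up.wedge & right.wedge).sum() / right.wedge.sum()
        assert overlap < 0.05

    def test_zero_direction_rejected(self, disk_cell):
        with pytest.raises(ValueError):
            geo.partition_regions(disk_cell, direction=(0.0, 0.0))

    def test_disk_is_not_flagged(self, disk_cell):
        assert not geo.partition_regions(disk_cell, direction=(1.0, 0.0)).flagged


class TestRegionIntensity:
    def test_uniform_image_equal_means(self, disk_cell, disk_mask):
        ratio = ImagePlane(np.where(disk_mask, 2.5, np.nan))
        part = geo.partition_regions(disk_cell, direction=(1.0, 0.0))
        means = geo.region_intensity(ratio, part)
        assert all(v == pytest.approx(2.5) for v in means.values())

    def test_rim_enrichment_shows_in_leading_edge(self):
        masks, stacks, _ = sy.make_moving_mask(
            n_frames=1, base_radius_px=40, drift_px_per_frame=(0, 0),
            protrusion_amp=0.0,
            intensity_fields={"g": {"level": 1.0, "rim_factor": 2.0,
                                    "rim_depth_frac": 0.1}}, seed=0)
        cell = geo.CellMask.from_array(masks[0])
        img = ImagePlane(np.where(masks[0], stacks["g"].frames[0], np.nan))
        part = geo.partition_regions(cell, direction=(1.0, 0.0))
        means = geo.region_intensity(img, part)
        assert means["center"] == pytest.approx(1.0, abs=0.05)
        assert means["leading_edge"] > 1.5 * means["center"]

    def test_empty_region_gives_nan(self, disk_cell, disk_mask):
        part = geo.partition_regions(disk_cell, direction=(1.0, 0.0),
                                     bands=((0.0, 0.0), (0.0, 0.5), (0.5, 1.0)))
        means = geo.region_intensity(ImagePlane(disk_mask * 1.0), part)
        assert np.isnan(means["leading_edge"])


class TestBoundaryWindows:
    def test_600_pixels_make_60_windows_of_10(self):
        pts = np.stack([np.zeros(600, dtype=int), np.arange(600)], axis=1)
        contour = geo.BoundaryContour(pixels=pts)
        win = geo.boundary_windows(contour, n=60)
        assert win.n_windows == 60
        assert all(len(w) == 10 for w in win.window_index)

    def test_window_sizes_differ_by_at_most_one(self, disk_cell):
        contour = geo.trace_boundary(disk_cell)
        win = geo.boundary_windows(contour, n=60)
        sizes = [len(w) for w in win.window_index]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(contour)

    def test_anchor_is_topmost_pixel(self, disk_cell):
        contour = geo.trace_boundary(disk_cell)
        win = geo.boundary_windows(contour, n=60)
        pts = contour.pixels
        top = pts[np.lexsort((pts[:, 1], pts[:, 0]))][0]
        assert tuple(win.contour.pixels[0]) == tuple(top)

    def test_too_few_pixels_rejected(self):
        pts = np.stack([np.zeros(30, dtype=int), np.arange(30)], axis=1)
        with pytest.raises(ValueError):
            geo.boundary_windows(geo.BoundaryContour(pixels=pts), n=60)

    def test_window_intensity_uniform_image(self, disk_cell):
        win = geo.boundary_windows(geo.trace_boundary(disk_cell), n=60)
        vals = geo.window_intensity(win, ImagePlane(np.full((128, 128), 9.0)))
        assert np.allclose(vals, 9.0)


class TestEdgeVelocity:
    def test_identical_masks_zero_velocity(self, disk_cell):
        win = geo.boundary_windows(geo.trace_boundary(disk_cell), n=60)
        v = geo.edge_velocity(disk_cell, disk_cell, win)
        assert np.allclose(v, 0.0)

    def test_uniform_dilation_two_px_per_frame(self, disk_mask):
        cell0 = geo.CellMask.from_array(disk_mask)
        cell1 = geo.CellMask.from_array(_euclid_dilate(disk_mask, 2.0))
        win = geo.boundary_windows(geo.trace_boundary(cell0), n=60)
        v = geo.edge_velocity(cell0, cell1, win)
        assert np.all(np.abs(v - 2.0) <= 0.5)

    def test_erosion_gives_negative_velocity(self, disk_mask):
        cell0 = geo.CellMask.from_array(disk_mask)
        eroded = ndimage.distance_transform_edt(disk_mask) > 2.0
        cell1 = geo.CellMask.from_array(eroded)
        win = geo.boundary_windows(geo.trace_boundary(cell0), n=60)
        assert np.all(geo.edge_velocity(cell0, cell1, win) < 0)

    def test_dt_scales_velocity(self, disk_mask):
        cell0 = geo.CellMask.from_array(disk_mask)
        cell1 = geo.CellMask.from_array(_euclid_dilate(disk_mask, 2.0))
        win = geo.boundary_windows(geo.trace_boundary(cell0), n=60)
        v1 = geo.edge_velocity(cell0, cell1, win, dt=1.0)
        v2 = geo.edge_velocity(cell0, cell1, win, dt=2.0)
        assert np.allclose(v2, v1 / 2.0)


class TestCorrelation:
    def test_perfectly_coupled_signals(self):
        v = np.linspace(-2, 2, 30)
        r, _ = geo.intensity_velocity_correlation(3 * v + 1, v)
        assert r == pytest.approx(1.0)
        r, _ = geo.intensity_velocity_correlation(-2 * v, v)
        assert r == pytest.approx(-1.0)

    def test_shuffled_signal_weak_correlation(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=500)
        i = rng.permutation(3 * v)
        r, p = geo.intensity_velocity_correlation(i, v)
        assert abs(r) < 0.15


class TestKymograph:
    def _stack(self, frames):
        return ImageStack(np.asarray(frames, dtype=float), frame_interval_s=1.0)

    def test_static_stack_constant_rows(self):
        img = np.tile(np.arange(16, dtype=float), (16, 1))
        stack = self._stack([img] * 5)
        path = np.stack([np.full(10, 8.0), np.linspace(0, 15, 10)], axis=1)
        kymo = geo.kymograph(stack, path)
        assert kymo.shape == (10, 5)
        assert np.allclose(kymo, kymo[:, :1])

    def test_moving_band_makes_diagonal(self):
        frames = []
        for t in range(6):
            f = np.zeros((8, 16))
            f[:, 2 + 2 * t] = 100.0
            frames.append(f)
        path = np.stack([np.full(16, 4.0), np.arange(16, dtype=float)], axis=1)
        kymo = geo.kymograph(self._stack(frames), path)
        peaks = kymo.argmax(axis=0)
        assert list(peaks) == [2 + 2 * t for t in range(6)]

    def test_out_of_frame_path_rejected(self):
        stack = self._stack([np.zeros((8, 8))])
        with pytest.raises(IndexError):
            geo.kymograph(stack, np.array([[4.0, 10.0]]))


class TestShapeDescriptors:
    def test_disk_metrics(self, disk_cell):
        sd = geo.shape_descriptors(disk_cell)
        assert sd.area_um2 == pytest.approx(np.pi * 40**2, rel=0.02)
        assert sd.aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert sd.circularity == pytest.approx(1.0, abs=0.1)

    def test_square_circularity_near_pi_over_4(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[10:60, 10:60] = True  # 50 px square
        sd = geo.shape_descriptors(geo.CellMask.from_array(mask))
        assert sd.circularity == pytest.approx(np.pi / 4, rel=0.1)

    def test_rectangle_aspect_ratio(self):
        mask = np.zeros((80, 120), dtype=bool)
        mask[20:60, 10:90] = True  # 40 x 80
        sd = geo.shape_descriptors(geo.CellMask.from_array(mask))
        assert sd.aspect_ratio == pytest.approx(2.0, rel=0.05)

    def test_pixel_size_scaling(self, disk_cell):
        a = geo.shape_descriptors(disk_cell, pixel_size_um=1.0)
        b = geo.shape_descriptors(disk_cell, pixel_size_um=0.5)
        assert b.area_um2 == pytest.approx(a.area_um2 / 4)
        assert b.perimeter_um == pytest.approx(a.perimeter_um / 2)
        assert b.circularity == pytest.approx(a.circularity)
        assert b.aspect_ratio == pytest.approx(a.aspect_ratio)


class TestEndToEndDrift:
    def test_drift_direction_recovered_from_mask_movie(self):
        masks, stacks, gt = sy.make_moving_mask(
            n_frames=12, drift_px_per_frame=(1, 0), protrusion_amp=0.0,
            intensity_fields={"g": {"level": 100.0}}, seed=8)
        cells = [geo.segment_cell(ImagePlane(f))
                 for f in stacks["g"].frames]
        traj = geo.centroid_trajectory([c.mask for c in cells], dt_min=1.0)
        d = windowed_direction(traj, 5)
        assert np.allclose(d, (1.0, 0.0), atol=0.5)
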