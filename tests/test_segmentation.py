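import numpy as np
import pytest
from scipy import ndimage

from conftest import three_population_image
from mctrace.mct import correlation_curve, transition_thresholds
from mctrace.raster_io import SectionImage
from mctrace.segmentation import (CellFilterParams, circularity,
                                  contour_perimeter, filter_components,
                                  find_cells, group_pixels, median_filter,
                                  rasterize_contour, smooth_boundary,
                                  trace_boundary)
from mctrace.synthetic import IntensityModel, RegionSpec, SyntheticBrainSpec, generate


def union_find_components(coords: list[tuple[int, int]], connectivity: int) -> int:
    """Brute-force component count oracle."""
    parent = list(range(len(coords)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (r1, c1) in enumerate(coords):
        for j in range(i):
            r2, c2 = coords[j]
            dr, dc = abs(r1 - r2), abs(c1 - c2)
            adjacent = (dr <= 1 and dc <= 1) if connectivity == 8 \
                else (dr + dc == 1)
            if adjacent:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(len(coords))})


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((6, 6), 42)
        assert np.array_equal(median_filter(img, 3), img)

    def test_hot_pixel_removed(self):
        img = np.zeros((7, 7))
        img[3, 3] = 255
        assert not median_filter(img, 3).any()

    def test_window_one_is_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (5, 5))
        assert np.array_equal(median_filter(img, 1), img)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((4, 4)), 4)


class TestMooreTrace:
    def test_single_pixel(self):
        m = np.zeros((3, 3), np.uint8)
        m[1, 1] = 1
        bds = trace_boundary(m)
        assert len(bds) == 1
        assert bds[0].contour.tolist() == [[1, 1]]

    def test_solid_square_perimeter_clockwise(self):
        m = np.zeros((5, 5), np.uint8)
        m[1:4, 1:4] = 1
        contour = trace_boundary(m)[0].contour.tolist()
        assert contour == [[1, 1], [1, 2], [1, 3], [2, 3], [3, 3],
                           [3, 2], [3, 1], [2, 1]]

    def test_two_objects_two_contours(self):
        m = np.zeros((8, 8), np.uint8)
        m[1:3, 1:3] = 1
        m[5:7, 5:7] = 1
        assert len(trace_boundary(m)) == 2

    def test_empty_mask(self):
        assert trace_boundary(np.zeros((4, 4), np.uint8)) == []

    def test_contour_pixels_are_boundary_pixels(self):
        rng = np.random.default_rng(7)
        blob = ndimage.binary_dilation(rng.random((20, 20)) > 0.93,
                                       iterations=2)
        lab, n = ndimage.label(blob, structure=np.ones((3, 3)))
        for b in trace_boundary(blob.astype(np.uint8)):
            for r, c in b.contour:
                assert blob[r, c]
                neigh = blob[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
                assert not neigh.all() or r in (0, 19) or c in (0, 19)

    def test_contour_path_is_8_connected_and_closed(self):
        m = np.zeros((9, 9), np.uint8)
        m[2:7, 2:7] = 1
        m[4, 4] = 1
        cont = trace_boundary(m)[0].contour
        closed = np.vstack([cont, cont[:1]])
        steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
        assert np.all(steps <= 1)


class TestSmoothBoundary:
    def test_sigma_zero_identity(self):
        m = np.zeros((6, 6), np.uint8)
        m[2:4, 2:4] = 1
        b = trace_boundary(m)[0]
        sm = smooth_boundary(b, 0.0, m.shape)
        assert np.array_equal(sm, rasterize_contour(b, m.shape))

    def test_mass_preserved(self):
        m = np.zeros((21, 21), np.uint8)
        m[10, 10] = 1
        b = trace_boundary(m)[0]
        sm = smooth_boundary(b, 1.0, m.shape)
        assert abs(sm.sum() - 1.0) < 1e-6

    def test_smoothing_raises_correlation_of_jittered_circles(self):
        rng = np.random.default_rng(0)
        shape = (64, 64)
        yy, xx = np.mgrid[0:64, 0:64]

        def circle_mask(jitter):
            rad = 20 + (rng.normal(0, jitter, (64, 64)) if jitter else 0)
            return ((yy - 32) ** 2 + (xx - 32) ** 2 <= rad ** 2).astype(np.uint8)

        clean = trace_boundary(circle_mask(0))[0]
        noisy = trace_boundary(circle_mask(1.5))[0]

        def corr(a, b):
            a, b = a.ravel() - a.mean(), b.ravel() - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        raw = corr(rasterize_contour(clean, shape), rasterize_contour(noisy, shape))
        smooth = corr(smooth_boundary(clean, 2.0, shape),
                      smooth_boundary(noisy, 2.0, shape))
        assert smooth > raw

    def test_negative_sigma_rejected(self):
        m = np.zeros((4, 4), np.uint8)
        m[1, 1] = 1
        with pytest.raises(ValueError):
            smooth_boundary(trace_boundary(m)[0], -1.0, m.shape)


class TestGroupPixels:
    def test_empty_mask_no_groups(self):
        assert group_pixels(np.zeros((5, 5), np.uint8)) == []

    def test_diagonal_connectivity_semantics(self):
        m = np.zeros((4, 4), np.uint8)
        m[1, 1] = m[2, 2] = 1
        assert len(group_pixels(m, 8)) == 1
        assert len(group_pixels(m, 4)) == 2

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        m = (rng.random((30, 30)) > 0.7).astype(np.uint8)
        groups = group_pixels(m, 8)
        assert sum(len(g) for g in groups) == m.sum()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_union_find_oracle(self, connectivity):
        rng = np.random.default_rng(11)
        m = np.zeros((40, 40), np.uint8)
        idx = rng.choice(1600, size=100, replace=False)
        m.ravel()[idx] = 1
        coords = list(zip(*np.nonzero(m)))
        expected = union_find_components(coords, connectivity)
        assert len(group_pixels(m, connectivity)) == expected

    def test_bad_connectivity(self):
        with pytest.raises(ValueError):
            group_pixels(np.ones((2, 2), np.uint8), 6)


class TestFilterComponents:
    def test_specks_removed_by_min_area(self):
        m = np.zeros((10, 10), np.uint8)
        m[1, 1] = m[5, 5] = m[8, 2] = 1
        groups = group_pixels(m)
        assert filter_components(groups, 5, 100, 0.0) == []

    def test_line_removed_disc_kept_by_roundness(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = ((yy - 10) ** 2 + (xx - 10) ** 2 <= 9).astype(np.uint8)
        line = np.zeros((40, 40), np.uint8)
        line[30, 5:35] = 1
        groups = group_pixels((disc | line).astype(np.uint8))
        cells = filter_components(groups, 1, 1000, 0.5)
        assert len(cells) == 1
        assert cells[0].roundness >= 0.5

    def test_disc_circularity_near_one_line_decreasing(self):
        yy, xx = np.mgrid[0:30, 0:30]
        disc = np.column_stack(np.nonzero((yy - 15) ** 2 + (xx - 15) ** 2 <= 16))
        assert 0.85 < circularity(disc) <= 1.15
        prev = circularity(disc)
        for length in (8, 16, 24):
            bar = np.column_stack([np.zeros(length, int), np.arange(length)])
            val = circularity(bar)
            assert val < prev
            prev = val

    def test_oversize_blob_removed(self):
        blob = np.ones((30, 30), np.uint8)
        groups = group_pixels(blob)
        assert filter_components(groups, 1, 400, 0.0) == []

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            filter_components([], 10, 5, 0.0)

    def test_perimeter_of_single_pixel_is_zero(self):
        assert contour_perimeter(np.array([[3, 3]])) == 0.0


class TestFindCells:
    def _section(self):
        img, mask, centers = three_population_image(n_cells=20, seed=3)
        return SectionImage(img), centers

    def test_recovers_separated_somata_with_close_centroids(self):
        sec, centers = self._section()
        cells = find_cells(sec, 150)
        assert len(cells) == 20
        got = np.array([c.centroid_px for c in cells])
        for r, c in centers:
            d = np.sqrt(((got - (r, c)) ** 2).sum(axis=1)).min()
            assert d < 2.0

    def test_roi_restricts_output(self):
        sec, centers = self._section()
        roi = np.zeros(sec.shape, np.uint8)
        roi[:, :sec.shape[1] // 2] = 1
        cells = find_cells(sec, 150, roi_mask=roi)
        assert all(c.centroid_px[1] < sec.shape[1] // 2 for c in cells)
        n_left = sum(1 for _, c in centers if c < sec.shape[1] // 2 - 3)
        assert len(cells) >= n_left - 1

    def test_blank_section_empty(self):
        sec = SectionImage(np.zeros((64, 64), np.uint8))
        assert find_cells(sec, 10) == []

    def test_deterministic(self):
        sec, _ = self._section()
        a = find_cells(sec, 150)
        b = find_cells(sec, 150)
        assert [c.centroid_px for c in a] == [c.centroid_px for c in b]

    def test_low_density_recovery_rate(self):
        """At low density with no deliberate overlaps, the detected count
        matches truth on >= 95% of seeded sections."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            spec = SyntheticBrainSpec(
                n_sections=1, section_shape=(256, 256), axes=(90.0, 70.0),
                regions=[RegionSpec(name="t", label=1, n_cells=30,
                                    min_spacing_px=7.0)],
                seed=seed,
            )
            sections, _, truth = generate(spec)
            sec = sections[0]
            curve = correlation_curve(median_filter(sec.pixels, 3), 8)
            sel = transition_thresholds(curve)
            cells = find_cells(sec, sel.cell_threshold)
            if len(cells) == len(truth.cells):
                hits += 1
        assert hits / n_rep >= 0.95
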