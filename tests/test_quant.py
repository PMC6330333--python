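import numpy as np
import pandas as pd
import pytest

from mctrace.alignment import SectionTransform
from mctrace.quant import (RegionTable, StructuralError, axis_distribution,
                           build_reconstruction, compartment_ratio,
                           density_map, injection_site_report,
                           region_assignment)
from mctrace.raster_io import SectionImage
from mctrace.segmentation import DetectedCell


def make_cell(row, col, rc=0):
    return DetectedCell(centroid_px=(row, col), centroid_um=(0, 0, 0),
                        area_px=10, roundness=0.9, mean_intensity=200.0,
                        rc_index=rc)


def simple_recon(cells, masks, names, n_sections=2, pixel_size=1.0,
                 thickness=100.0, transforms=None, flags=None):
    sections = [SectionImage(np.zeros((32, 32), np.uint8), pixel_size=pixel_size,
                             thickness=thickness, rc_index=i)
                for i in range(n_sections)]
    transforms = transforms or [SectionTransform(i, (0, 0), 1.0)
                                for i in range(n_sections)]
    return build_reconstruction(
        sections, transforms, [None] * n_sections, cells,
        region_labels=masks,
        region_table=RegionTable(names=names, flags=flags or {}),
    )


class TestBuildReconstruction:
    def test_z_is_rc_times_thickness(self):
        cells = [make_cell(4, 6, rc=0), make_cell(4, 6, rc=1)]
        recon = simple_recon(cells, None, {}, pixel_size=1.0, thickness=100.0)
        assert recon.cells["z_um"].tolist() == [0.0, 100.0]

    def test_shift_moves_coordinates_before_scaling(self):
        cells = [make_cell(10, 20, rc=1)]
        tr = [SectionTransform(0, (0, 0), 1.0), SectionTransform(1, (10, -5), 1.0)]
        recon = simple_recon(cells, None, {}, transforms=tr, pixel_size=2.0)
        assert recon.cells.loc[0, "y_um"] == (10 + 10) * 2.0
        assert recon.cells.loc[0, "x_um"] == (20 - 5) * 2.0

    def test_missing_transform_is_structural_error(self):
        cells = [make_cell(1, 1, rc=1)]
        sections = [SectionImage(np.zeros((8, 8), np.uint8), rc_index=i)
                    for i in range(2)]
        with pytest.raises(StructuralError):
            build_reconstruction(sections, [SectionTransform(0, (0, 0), 1.0)],
                                 [None, None], cells)


def nested_masks(n_sections=1, shape=(32, 32)):
    """Label 2 = inner layer disc, label 1 = surrounding organ ring."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (yy - 16) ** 2 + (xx - 16) ** 2
    mask = np.zeros(shape, np.int16)
    mask[d2 <= 196] = 1
    mask[d2 <= 36] = 2
    return [mask.copy() for _ in range(n_sections)]


class TestInjectionSite:
    names = {1: "MOB", 2: "GCL"}

    def test_all_inside_gives_fraction_one(self):
        cells = [make_cell(16, 16), make_cell(17, 15)]
        recon = simple_recon(cells, nested_masks(), self.names, n_sections=1)
        rep = injection_site_report(recon, "MOB", "GCL")
        assert rep.fraction_inside == 1.0

    def test_center_of_mass_is_arithmetic_mean(self):
        # one cell in the layer (rc 0), one in the organ ring (rc 1)
        cells = [make_cell(16, 16, rc=0), make_cell(16, 26, rc=1)]
        recon = simple_recon(cells, nested_masks(2), self.names, n_sections=2)
        rep = injection_site_report(recon, "MOB", "GCL")
        assert rep.center_of_mass == (21.0, 16.0, 50.0)

    def test_counts_split_by_layer_membership(self):
        inside = [make_cell(16, 16), make_cell(14, 17), make_cell(18, 15)]
        outside = [make_cell(16, 27), make_cell(5, 16)]
        recon = simple_recon(inside + outside, nested_masks(), self.names,
                             n_sections=1)
        rep = injection_site_report(recon, "MOB", "GCL")
        assert (rep.n_inside, rep.n_outside) == (3, 2)
        assert rep.fraction_inside == 0.6

    def test_empty_organ_flagged(self):
        recon = simple_recon([make_cell(0, 0)], nested_masks(), self.names,
                             n_sections=1)
        rep = injection_site_report(recon, "MOB", "GCL")
        assert rep.empty


class TestAxisDistribution:
    def test_single_plane_single_bin(self):
        cells = [make_cell(10, c, rc=0) for c in range(5, 25)]
        recon = simple_recon(cells, None, {}, n_sections=1)
        frac, edges = axis_distribution(recon, None, "RC", n_bins=4)
        assert frac.sum() == pytest.approx(1.0)
        assert (frac > 0).sum() == 1

    def test_uniform_positions_give_uniform_histogram(self):
        rng = np.random.default_rng(0)
        cells = [make_cell(r, c, rc=0)
                 for r, c in rng.uniform(0, 31, (10000, 2))]
        recon = simple_recon(cells, None, {}, n_sections=1)
        frac, _ = axis_distribution(recon, None, "ML", n_bins=10)
        counts = frac * 10000
        chi2 = ((counts - 1000) ** 2 / 1000).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2_dist.sf(chi2, 9) > 0.01

    def test_empty_region_gives_empty_histogram(self):
        recon = simple_recon([make_cell(16, 16)], nested_masks(), {1: "A", 2: "B"},
                             n_sections=1)
        frac, _ = axis_distribution(recon, "A", "DV")
        assert frac.size == 0

    def test_bad_axis_rejected(self):
        recon = simple_recon([make_cell(1, 1)], None, {}, n_sections=1)
        with pytest.raises(ValueError):
            axis_distribution(recon, None, "XY")


class TestDensityMap:
    def test_single_cell_single_count(self):
        recon = simple_recon([make_cell(10, 10)], None, {}, n_sections=1)
        counts, _, _ = density_map(recon, "coronal", bin_um=50)
        assert counts.sum() == 1

    def test_total_conserved(self):
        rng = np.random.default_rng(4)
        cells = [make_cell(r, c, rc=int(z)) for r, c, z in
                 zip(rng.uniform(0, 31, 200), rng.uniform(0, 31, 200),
                     rng.integers(0, 2, 200))]
        recon = simple_recon(cells, None, {}, n_sections=2)
        counts, _, _ = density_map(recon, "sagittal", bin_um=20)
        assert counts.sum() == 200

    def test_normalized_to_injection_site_centers_mass(self):
        cells = [make_cell(10, 10), make_cell(12, 12)]
        recon = simple_recon(cells, None, {}, n_sections=1)
        com = (11.0, 11.0, 0.0)
        counts, ve, he = density_map(recon, "coronal", bin_um=5,
                                     normalize_to=com)
        assert ve.min() <= 0 <= ve.max()

    def test_ventral_concentration_detected(self):
        rng = np.random.default_rng(9)
        rows = np.concatenate([rng.uniform(20, 31, 900), rng.uniform(0, 20, 100)])
        cells = [make_cell(r, 16) for r in rows]
        recon = simple_recon(cells, None, {}, n_sections=1)
        counts, ve, _ = density_map(recon, "coronal", bin_um=4)
        centers = (ve[:-1] + ve[1:]) / 2
        below = counts[centers > 15.5].sum()
        assert below / counts.sum() > 0.8


class TestRegionAssignment:
    def test_all_cells_one_region_is_100_percent(self):
        cells = [make_cell(16, 16), make_cell(15, 17)]
        recon = simple_recon(cells, nested_masks(), {1: "A", 2: "B"},
                             n_sections=1)
        rep = region_assignment(recon)
        assert rep.percentages["B"] == 100.0

    def test_percentages_sum_to_100_and_conserve(self):
        rng = np.random.default_rng(2)
        cells = [make_cell(r, c) for r, c in rng.integers(0, 32, (300, 2))]
        recon = simple_recon(cells, nested_masks(), {1: "A", 2: "B"},
                             n_sections=1)
        rep = region_assignment(recon)
        assert sum(rep.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert rep.n_assigned + rep.n_unassigned == len(cells)

    def test_missing_mask_is_structural_error(self):
        recon = simple_recon([make_cell(1, 1)], None, {}, n_sections=1)
        with pytest.raises(StructuralError):
            region_assignment(recon)

    def test_translation_equivariance(self):
        """Shifting sections and masks together leaves every report unchanged."""
        rng = np.random.default_rng(6)
        cells = [make_cell(r, c) for r, c in rng.integers(4, 24, (50, 2))]
        masks = nested_masks()
        recon = simple_recon(cells, masks, {1: "A", 2: "B"}, n_sections=1)
        rep = region_assignment(recon)

        moved_cells = [make_cell(c.centroid_px[0] + 3, c.centroid_px[1] + 5)
                       for c in cells]
        moved_masks = [np.roll(np.roll(m, 3, axis=0), 5, axis=1) for m in masks]
        recon2 = simple_recon(moved_cells, moved_masks, {1: "A", 2: "B"},
                              n_sections=1)
        rep2 = region_assignment(recon2)
        assert rep.counts == rep2.counts

    def test_subsampling_stability(self):
        rng = np.random.default_rng(8)
        cells = [make_cell(r, c) for r, c in rng.integers(2, 30, (4000, 2))]
        recon = simple_recon(cells, nested_masks(), {1: "A", 2: "B"},
                             n_sections=1)
        full = region_assignment(recon).percentages
        keep = rng.choice(len(cells), size=2000, replace=False)
        sub = region_assignment(
            simple_recon([cells[i] for i in keep], nested_masks(),
                         {1: "A", 2: "B"}, n_sections=1)).percentages
        for name in full:
            assert abs(full[name] - sub[name]) < 3.0


class TestCompartmentRatio:
    def test_empty_b_gives_share_one(self):
        cells = [make_cell(16, 16), make_cell(15, 16)]
        recon = simple_recon(cells, nested_masks(), {2: "MOB", 1: "AOB"},
                             n_sections=1)
        out = compartment_ratio(recon, "MOB", "AOB")
        assert out["share_a"] == 1.0 and out["count_b"] == 0

    def test_both_empty_flagged_undefined(self):
        recon = simple_recon([], nested_masks(), {1: "MOB", 2: "AOB"},
                             n_sections=1)
        out = compartment_ratio(recon, "MOB", "AOB")
        assert out["undefined"]

    def test_counts_exact(self):
        a = [make_cell(16, 16)] * 3          # layer disc, label 2
        b = [make_cell(16, 27)] * 2          # ring, label 1
        recon = simple_recon(a + b, nested_masks(), {2: "X", 1: "Y"},
                             n_sections=1)
        out = compartment_ratio(recon, "X", "Y")
        assert (out["count_a"], out["count_b"]) == (3, 2)
        assert out["share_a"] == pytest.approx(0.6)
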