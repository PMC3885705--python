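"""Threshold, particle filters and per-tile segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctcmorph.config import DEFAULT_CONFIG
from ctcmorph.errors import DegenerateImageError
from ctcmorph.segmentation import (FLAG_BORDER, FLAG_EMPTY, FLAG_MULTI,
                                   cluster_threshold, debris_filter,
                                   detect_multi_particle, label_particles,
                                   reject_border_particles, segment_tile,
                                   stabilized_threshold)
from ctcmorph.synth import CellTruth, EllipseSpec, GalleryConfig, render_tile

from .conftest import erode_3x3, exhaustive_otsu, raster_ellipse


class TestClusterThreshold:
    def test_perfectly_separable_two_values(self):
        img = np.where(np.arange(100).reshape(10, 10) % 3 == 0, 200, 10)
        img = img.astype(np.uint8)
        mask, t = cluster_threshold(img)
        assert 10 <= t < 200
        np.testing.assert_array_equal(mask, img == 200)

    def test_two_point_masses_cut_between_modes(self):
        img = np.concatenate([np.full(60, 50), np.full(40, 180)])
        img = img.astype(np.uint8).reshape(10, 10)
        _, t = cluster_threshold(img)
        assert 50 <= t < 180

    def test_matches_exhaustive_search_on_bimodal(self, bimodal_image):
        _, t = cluster_threshold(bimodal_image)
        assert t == exhaustive_otsu(bimodal_image)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            cluster_threshold(np.full((16, 16), 42, dtype=np.uint8))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(arrays(np.uint8, (12, 12), elements=st.integers(0, 255)))
    def test_equals_oracle_on_random_images(self, img):
        """Vectorized cut always equals the naive 255-point search."""
        if img.min() == img.max():
            return
        _, t = cluster_threshold(img)
        assert t == exhaustive_otsu(img)


class TestStabilizedThreshold:
    def test_small_bright_object_on_large_noisy_tile(self):
        """A nucleus covering ~0.2% of the tile must still be isolated."""
        g = np.random.default_rng(3)
        side = 190
        img = g.normal(30, 10, (side, side))
        disk = raster_ellipse(95, 95, 5, 5, 0, side)
        img[disk] = g.normal(200, 10, int(disk.sum()))
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        mask, t = stabilized_threshold(img)
        assert 80 < t < 190  # cut sits in the intensity gap
        # recovered foreground equals the disk up to noise misclassification
        assert abs(int(mask.sum()) - int(disk.sum())) <= 2

    def test_noiseless_mask_is_exact(self):
        img = np.full((60, 60), 30, dtype=np.uint8)
        disk = raster_ellipse(30, 30, 8, 8, 0, 60)
        img[disk] = 180
        mask, _ = stabilized_threshold(img)
        np.testing.assert_array_equal(mask, disk)


class TestLabelParticles:
    def test_two_disjoint_squares(self):
        m = np.zeros((12, 12), dtype=bool)
        m[1:4, 1:4] = True
        m[7:10, 7:10] = True
        lab = label_particles(m)
        assert lab.n == 2
        assert sorted(lab.counts[1:].tolist()) == [9, 9]

    def test_diagonal_touch_joined_by_8_connectivity(self):
        m = np.zeros((8, 8), dtype=bool)
        m[1:3, 1:3] = True
        m[3:5, 3:5] = True  # touches only at corner (2,2)-(3,3)
        assert label_particles(m).n == 1
        assert label_particles(m, connectivity=4).n == 2

    def test_empty_mask(self):
        lab = label_particles(np.zeros((5, 5), dtype=bool))
        assert lab.n == 0
        assert lab.foreground_px == 0

    def test_raster_order_labels(self):
        m = np.zeros((10, 10), dtype=bool)
        m[6:9, 1:4] = True   # lower-left, later in raster order
        m[1:3, 5:8] = True   # upper-right, first
        lab = label_particles(m)
        assert lab.labels[1, 5] == 1
        assert lab.labels[6, 1] == 2


class TestBorderRejection:
    def test_edge_pixel_removes_particle(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3:6, 0:3] = True  # touches column 0
        lab = reject_border_particles(label_particles(m))
        assert lab.n == 0

    def test_interior_particle_kept(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1:9, 1:9] = True  # 1 px from every edge
        lab = reject_border_particles(label_particles(m))
        assert lab.n == 1
        assert lab.foreground_px == 64

    def test_survivors_relabeled_in_order(self):
        m = np.zeros((12, 12), dtype=bool)
        m[0:2, 0:2] = True    # border -> dropped
        m[4:6, 4:6] = True    # kept, becomes label 1
        m[8:10, 8:10] = True  # kept, becomes label 2
        lab = reject_border_particles(label_particles(m))
        assert lab.n == 2
        assert lab.labels[4, 4] == 1
        assert lab.labels[8, 8] == 2


class TestDebrisFilter:
    def test_3x3_square_dies_under_two_erosions(self):
        m = np.zeros((9, 9), dtype=bool)
        m[3:6, 3:6] = True
        # oracle: manual erosion twice
        assert not erode_3x3(erode_3x3(m)).any()
        lab = debris_filter(label_particles(m))
        assert lab.n == 0

    def test_10x10_square_survives_with_original_area(self):
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True
        once = erode_3x3(m)
        twice = erode_3x3(once)
        assert once.sum() == 64 and twice.sum() == 36  # 8x8 then 6x6
        lab = debris_filter(label_particles(m))
        assert lab.n == 1
        assert lab.foreground_px == 100  # original pixels retained

    def test_thin_line_dies(self):
        m = np.zeros((5, 24), dtype=bool)
        m[2, 2:22] = True
        assert debris_filter(label_particles(m)).n == 0

    def test_idempotent(self, rng):
        m = rng.random((40, 40)) < 0.45
        once = debris_filter(label_particles(m))
        twice = debris_filter(once)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_measure_eroded_variant(self):
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True
        lab = debris_filter(label_particles(m), measure_eroded=True)
        assert lab.foreground_px == 36  # 6x6 after two erosions

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(arrays(bool, (20, 20)))
    def test_filters_never_increase_foreground(self, m):
        lab = label_particles(m)
        total = lab.foreground_px
        after_border = reject_border_particles(lab)
        assert after_border.foreground_px <= total
        after_debris = debris_filter(after_border)
        assert after_debris.foreground_px <= after_border.foreground_px


class TestMultiParticle:
    def test_two_disjoint_blobs(self):
        m = np.zeros((40, 40), dtype=bool)
        m[5:15, 5:15] = True
        m[25:35, 25:35] = True
        assert detect_multi_particle(label_particles(m)) is True

    def test_single_convex_disk(self):
        m = raster_ellipse(30, 30, 12, 12, 0, 61)
        assert detect_multi_particle(label_particles(m)) is False

    def test_single_elongated_ellipse_not_split(self):
        m = raster_ellipse(40, 40, 24, 8, 30, 81)
        assert detect_multi_particle(label_particles(m)) is False

    def test_overlapping_disks_detected(self):
        # two r=12 disks, centers 18 px apart -> one 8-connected particle
        # with two EDT maxima ~18 px apart (> h_min) and two big basins
        rr, cc = np.mgrid[0:64, 0:64]
        m = (((rr - 32) ** 2 + (cc - 23) ** 2 <= 144)
             | ((rr - 32) ** 2 + (cc - 41) ** 2 <= 144))
        lab = label_particles(m)
        assert lab.n == 1
        assert detect_multi_particle(lab) is True


class TestSegmentTile:
    def _tile(self, truth, noise_sd=0.0, seed=5):
        cfg = GalleryConfig(n_tiles=1, noise_sd=noise_sd, seed=seed)
        return render_tile(truth, cfg, np.random.default_rng(seed))

    def test_clean_singlet_areas_match_rasterization_oracle(self, cfg):
        side = 100
        cell = EllipseSpec(49.5, 49.5, 14, 10, 25)
        nuc = EllipseSpec(49.5, 49.5, 9, 7, 25)
        truth = CellTruth(tile_id="x", case="singlet", side_px=side,
                          cells=(cell,), nuclei=(nuc,))
        tile = self._tile(truth, noise_sd=0.0)
        res = segment_tile(tile, cfg)
        assert res.flags == set()
        from .conftest import lattice_count
        assert res.a_cell_px == lattice_count(49.5, 49.5, 14, 10, 25, side)
        assert res.a_nuc_px == lattice_count(49.5, 49.5, 9, 7, 25, side)

    def test_border_cell_flagged(self, cfg):
        truth = CellTruth(tile_id="x", case="border_touch", side_px=90,
                          cells=(EllipseSpec(45, 2, 12, 10, 0),),
                          nuclei=(EllipseSpec(45, 6, 6, 5, 0),))
        tile = self._tile(truth, noise_sd=10.0)
        res = segment_tile(tile, cfg)
        assert FLAG_BORDER in res.flags

    def test_blank_tile_flagged_empty(self, cfg):
        truth = CellTruth(tile_id="x", case="blank", side_px=90)
        tile = self._tile(truth, noise_sd=10.0)
        res = segment_tile(tile, cfg)
        assert (FLAG_EMPTY in res.flags) or ("debris_only" in res.flags)
        assert FLAG_MULTI not in res.flags
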