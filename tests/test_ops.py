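"""Unit and property tests for the low-level image operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from embryostager import ops
from embryostager.errors import (
    ConfigurationError,
    DegenerateHistogramError,
    EmptyMaskError,
    NoMarkersError,
)
from conftest import random_int_image
import oracles


class TestMeanFilter:
    def test_constant_unchanged(self):
        img = np.full((7, 7), 5.0)
        assert np.array_equal(ops.mean_filter(img, 3), img)

    def test_single_impulse(self):
        img = np.zeros((5, 5))
        img[2, 2] = 9.0
        assert ops.mean_filter(img, 3)[2, 2] == pytest.approx(1.0)

    @pytest.mark.parametrize("size", [0, -1, 2, 4])
    def test_invalid_range_rejected(self, size):
        with pytest.raises(ConfigurationError):
            ops.mean_filter(np.zeros((4, 4)), size)


class TestLocalMeanThreshold:
    def test_constant_all_background(self):
        assert not ops.local_mean_threshold(np.full((6, 6), 3.0), 3).any()

    def test_single_bright_pixel(self):
        img = np.zeros((7, 7))
        img[3, 4] = 10.0
        mask = ops.local_mean_threshold(img, 3)
        assert mask[3, 4] and mask.sum() == 1

    def test_window_larger_than_image_uses_global_mean(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        assert np.array_equal(ops.local_mean_threshold(img, 99), img > img.mean())

    def test_offset_invariance(self, rng):
        img = random_int_image(rng, (10, 10))
        assert np.array_equal(
            ops.local_mean_threshold(img, 5),
            ops.local_mean_threshold(img + 7.0, 5),
        )


class TestOtsu:
    def test_bimodal_split(self):
        img = np.array([10.0] * 100 + [200.0] * 100).reshape(10, 20)
        mask = ops.otsu_threshold(img)
        assert mask.sum() == 100 and mask[img == 200].all()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            ops.otsu_threshold(np.full((5, 5), 1.0))


class TestFillHoles:
    def test_ring_becomes_disc(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[1:6, 1:6] = True
        mask[2:5, 2:5] = False
        filled = ops.fill_holes(mask)
        assert filled[2:5, 2:5].all()

    def test_idempotent(self, rng):
        for _ in range(20):
            mask = rng.random((9, 9)) < 0.4
            once = ops.fill_holes(mask)
            assert np.array_equal(once, ops.fill_holes(once))
            assert (once | mask).sum() == once.sum()  # never removes foreground


class TestLargestComponent:
    def test_keeps_bigger_blob(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True   # 9 px
        mask[6:8, 6:8] = True   # 4 px
        out = ops.largest_component(mask)
        assert out[1:4, 1:4].all() and not out[6:8, 6:8].any()

    def test_tie_breaks_to_first_in_raster_order(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[5, 0:2] = True          # later in raster order
        mask[0, 5:7] = True          # first in raster order, same size
        out = ops.largest_component(mask)
        assert out[0, 5:7].all() and not out[5].any()

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyMaskError):
            ops.largest_component(np.zeros((4, 4), dtype=bool))

    def test_idempotent(self, rng):
        for _ in range(20):
            mask = rng.random((9, 9)) < 0.35
            if not mask.any():
                continue
            once = ops.largest_component(mask)
            assert np.array_equal(once, ops.largest_component(once))


class TestConvexHullExtent:
    def test_rectangle(self):
        mask = np.zeros((20, 10), dtype=bool)
        mask[4:14, 2:6] = True
        _, extent = ops.convex_hull_extent(mask)
        assert extent == 10

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        vertices, extent = ops.convex_hull_extent(mask)
        assert extent == 1 and len(vertices) == 1

    def test_empty_rejected(self):
        with pytest.raises(EmptyMaskError):
            ops.convex_hull_extent(np.zeros((3, 3), dtype=bool))


class TestLogSeeds:
    @staticmethod
    def _spot(shape, centre, sigma, amp=100.0):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        return amp * np.exp(-(((yy - centre[0]) ** 2 + (xx - centre[1]) ** 2) / (2 * sigma ** 2)))

    def test_single_spot_single_seed(self):
        img = self._spot((50, 50), (25, 18), 3.0)
        seeds = ops.log_seeds(img, 1.5, 6.0)
        assert len(seeds) == 1
        assert np.abs(seeds.coords[0] - [25, 18]).max() <= 1

    def test_two_spots_two_seeds(self):
        img = self._spot((60, 60), (15, 15), 3.0) + self._spot((60, 60), (45, 42), 3.0)
        seeds = ops.log_seeds(img, 1.5, 6.0)
        assert len(seeds) == 2

    def test_flat_image_no_seeds(self):
        assert len(ops.log_seeds(np.zeros((30, 30)), 1.0, 5.0)) == 0

    def test_invalid_scales_rejected(self):
        with pytest.raises(ConfigurationError):
            ops.log_seeds(np.zeros((10, 10)), 5.0, 2.0)


class TestSeededWatershed:
    def test_single_seed_floods_everything(self, rng):
        relief = random_int_image(rng, (6, 6))
        labels = ops.seeded_watershed(relief, np.array([[3, 3]]))
        assert (labels == 1).all()

    def test_two_basins_split_at_ridge(self):
        relief = np.array([[0.0, 1.0, 5.0, 1.0, 0.0]])
        labels = ops.seeded_watershed(relief, np.array([[0, 0], [0, 4]]))
        assert labels[0, 0] == 1 and labels[0, 4] == 2
        assert set(np.unique(labels)) == {1, 2}

    def test_partition_of_mask(self, rng):
        for _ in range(10):
            relief = random_int_image(rng, (8, 8))
            mask = np.ones((8, 8), dtype=bool)
            labels = ops.seeded_watershed(relief, np.array([[0, 0], [7, 7]]), mask=mask)
            assert (labels > 0).sum() == mask.sum()

    def test_seed_outside_mask_dropped_with_warning(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0:2, 0:2] = True
        with pytest.warns(UserWarning):
            labels = ops.seeded_watershed(np.zeros((5, 5)), np.array([[0, 0], [4, 4]]), mask=mask)
        assert set(np.unique(labels)) == {0, 1}

    def test_no_markers_rejected(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(NoMarkersError), pytest.warns(UserWarning):
            ops.seeded_watershed(np.zeros((4, 4)), np.array([[3, 3]]), mask=mask)

    def test_3d_flood(self):
        relief = np.zeros((4, 4, 4))
        labels = ops.seeded_watershed(relief, np.array([[0, 0, 0]]))
        assert (labels == 1).all()


class TestApplyMaskAndBorders:
    def test_all_ones_mask_identity(self, rng):
        labels = (random_int_image(rng, (6, 6), 4)).astype(int)
        labels = oracles.apply_mask_oracle(labels, np.ones((6, 6), dtype=bool))
        assert np.array_equal(ops.apply_mask(labels, np.ones((6, 6), dtype=bool)), labels)

    def test_zero_mask_empties(self):
        labels = np.ones((4, 4), dtype=int)
        out = ops.apply_mask(labels, np.zeros((4, 4), dtype=bool))
        assert not out.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            ops.apply_mask(np.ones((3, 3), dtype=int), np.ones((4, 4), dtype=bool))

    def test_border_blob_removed_centre_kept(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[0:2, 3:5] = 1   # touches top edge
        labels[4:6, 4:6] = 2   # interior
        out = ops.remove_border_objects(labels)
        assert set(np.unique(out)) == {0, 1}
        assert (out[4:6, 4:6] == 1).all()


class TestRotateAboutY:
    def test_zero_angle_identity(self, rng):
        stack = rng.random((6, 5, 6))
        assert np.array_equal(ops.rotate_about_y(stack, 0.0), stack)

    def test_quarter_turn_moves_bar_to_orthogonal_axis(self):
        stack = np.zeros((9, 3, 9))
        stack[4, 1, 2:7] = 1.0  # bar along x
        rot = ops.rotate_about_y(stack, 90.0)
        z_extent = np.ptp(np.nonzero(rot > 0.5)[0])
        x_extent = np.ptp(np.nonzero(rot > 0.5)[2])
        assert z_extent > x_extent  # now aligned with z

    def test_round_trip_bounded_error(self, rng):
        stack = np.zeros((24, 8, 24))
        stack[8:16, 2:6, 8:16] = 100.0
        back = ops.rotate_about_y(ops.rotate_about_y(stack, 40.0), -40.0)
        # compare on the interior of the original, centred in the grown canvas
        dz = (back.shape[0] - stack.shape[0]) // 2
        dx = (back.shape[2] - stack.shape[2]) // 2
        core = back[dz + 10:dz + 14, 3:5, dx + 10:dx + 14]
        assert np.abs(core - 100.0).max() < 10.0

    def test_anisotropic_resampled_first(self):
        stack = np.zeros((10, 4, 20))
        out = ops.rotate_about_y(stack, 0.0, voxel_size=(2.0, 1.0, 1.0))
        assert out.shape == (20, 4, 20)  # z doubled to the 1 um grid

    def test_2d_input_rejected(self):
        with pytest.raises(ConfigurationError):
            ops.rotate_about_y(np.zeros((5, 5)), 10.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    img=hnp.arrays(
        dtype=np.int64,
        shape=st.tuples(st.integers(3, 9), st.integers(3, 9)),
        elements=st.integers(0, 15),
    ),
    offset=st.integers(1, 50),
)
def test_local_threshold_invariant_under_constant_offset(img, offset):
    """Adding a constant shifts image and local mean alike."""
    a = img.astype(float)
    assert np.array_equal(
        ops.local_mean_threshold(a, 3),
        ops.local_mean_threshold(a + offset, 3),
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    mask=hnp.arrays(
        dtype=bool,
        shape=st.tuples(st.integers(3, 9), st.integers(3, 9)),
    )
)
def test_fill_holes_never_removes_foreground_and_is_idempotent(mask):
    once = ops.fill_holes(mask)
    assert (once & mask).sum() == mask.sum()
    assert np.array_equal(once, ops.fill_holes(once))
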