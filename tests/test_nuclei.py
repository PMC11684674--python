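"""Tests for nuclei morphometrics and pole-cell counting."""

import numpy as np
import pytest

from embryostager import nuclei, ops, synth
from embryostager.errors import ConfigurationError
from embryostager.nuclei import NucleiConfig, NucleiStats, PoleCellConfig, PoleCellCount

MATCHED_CFG = NucleiConfig(gauss_range=2.0, local_range=15, log_scales=(2.0, 5.0))


def _embryo_frame(seed=0):
    spec = synth.SyntheticEmbryoSpec(rng_seed=seed, frame_shape=(512, 256))
    frames, truth = synth.generate_embryo_movie(spec)
    return frames[0], truth


class TestExtractPosteriorWindow:
    def test_window_position_from_known_posterior(self):
        frame, _ = _embryo_frame(seed=1)
        window, (r0, c0) = nuclei.extract_posterior_window(frame, offset=120, size=100)
        mask = ops.otsu_threshold(frame)
        posterior = np.nonzero(mask.any(axis=1))[0].max()
        assert r0 == posterior - 120 - 50
        assert window.shape == (100, 100)

    def test_mirrored_frame_flipped_convention(self):
        frame, _ = _embryo_frame(seed=2)
        w1, (r1, _) = nuclei.extract_posterior_window(frame, offset=120, size=100,
                                                      posterior_end="max_y")
        w2, (r2, _) = nuclei.extract_posterior_window(frame[::-1], offset=120, size=100,
                                                      posterior_end="min_y")
        # same window up to the one-row parity shift of an even-sized box
        flipped = w2[::-1]
        assert any(
            np.array_equal(w1[1:], flipped[:-1]) or np.array_equal(w1, flipped)
            or np.array_equal(w1[:-1], flipped[1:])
            for _ in [0]
        )

    def test_window_exceeding_bounds_rejected(self):
        frame, _ = _embryo_frame(seed=1)
        with pytest.raises(ConfigurationError, match="bounds"):
            nuclei.extract_posterior_window(frame, offset=500, size=150)

    def test_empty_frame_rejected(self):
        with pytest.raises(Exception):
            nuclei.extract_posterior_window(np.zeros((300, 200)))


class TestSegmentNuclei2d:
    def test_well_separated_spots_counted_exactly(self):
        img, truth = synth.generate_nuclei_window(25, sigma=3.0, seed=5)
        labels = nuclei.segment_nuclei_2d(img, MATCHED_CFG)
        assert labels.n_objects == truth.count == 25

    def test_signal_free_window_zero_objects(self):
        img, _ = synth.generate_nuclei_window(0, seed=6, poisson=False, read_noise_sd=0.0)
        with pytest.warns(UserWarning):
            labels = nuclei.segment_nuclei_2d(img, MATCHED_CFG)
        assert labels.n_objects == 0

    def test_touching_spots_split_by_watershed(self):
        """Two spots joined across a ridge are separated into two objects."""
        yy, xx = np.mgrid[:60, :60]
        img = 100.0 + 500 * np.exp(-(((yy - 30) ** 2 + (xx - 24) ** 2) / 18.0))
        img += 500 * np.exp(-(((yy - 30) ** 2 + (xx - 37) ** 2) / 18.0))
        cfg = NucleiConfig(gauss_range=1.0, local_range=15, log_scales=(2.0, 4.0))
        labels = nuclei.segment_nuclei_2d(img, cfg)
        assert labels.n_objects == 2

    def test_count_invariant_to_offset_and_rotation(self):
        img, _ = synth.generate_nuclei_window(20, sigma=3.0, seed=7)
        n0 = nuclei.segment_nuclei_2d(img, MATCHED_CFG).n_objects
        n_off = nuclei.segment_nuclei_2d(img + 50.0, MATCHED_CFG).n_objects
        n_rot = nuclei.segment_nuclei_2d(np.rot90(img).copy(), MATCHED_CFG).n_objects
        assert n_off == n0
        assert abs(n_rot - n0) <= 1


class TestNucleiStats:
    def test_empty_labelmap_zero_stats(self):
        from embryostager.types import LabelMap

        stats = nuclei.nuclei_stats(LabelMap(np.zeros((50, 50), dtype=int)))
        assert stats.count == 0 and stats.density_per_px2 == 0.0

    def test_mean_area_matches_threshold_model(self):
        """Measured area of isolated flat-core nuclei tracks a numeric
        local-mean threshold oracle within 10 %."""
        img, truth = synth.generate_nuclei_window(
            8, sigma=2.0, core_radius=6.0, amplitude=600, background=100,
            poisson=False, read_noise_sd=0.0, seed=8,
        )
        cfg = NucleiConfig(gauss_range=2.0, local_range=15, log_scales=(3.0, 6.0))
        stats = nuclei.nuclei_stats(nuclei.segment_nuclei_2d(img, cfg))
        assert stats.count == 8
        # oracle: area where a smoothed spot exceeds the local box mean,
        # computed from first principles on a single-spot tile
        from scipy.ndimage import gaussian_filter, uniform_filter

        tile = np.zeros((101, 101))
        yy, xx = np.mgrid[:101, :101]
        r = np.sqrt((yy - 50.0) ** 2 + (xx - 50.0) ** 2)
        tile += 600 * np.exp(-0.5 * np.clip(r - 6.0, 0, None) ** 2 / 4.0)
        sm = gaussian_filter(tile + 100, 2.0, mode="nearest")
        local_mean = uniform_filter(sm, 15, mode="nearest")
        # epsilon guards against float fuzz on the flat background far from
        # the spot, where the true margin is exactly zero
        expected = int((sm > local_mean + 1e-3).sum())
        assert stats.mean_area_px == pytest.approx(expected, rel=0.10)

    def test_density_doubles_with_count(self):
        a = NucleiStats("t", 10, np.ones(10) * 20, window_area_px=150 * 150)
        b = NucleiStats("t", 20, np.ones(20) * 20, window_area_px=150 * 150)
        assert b.density_per_px2 / a.density_per_px2 == pytest.approx(2.0)

    def test_count_must_match_areas(self):
        with pytest.raises(ConfigurationError):
            NucleiStats("t", 3, np.ones(2), window_area_px=100.0)


class TestDivisionRatios:
    def test_identical_stats_unit_ratios(self):
        s = NucleiStats("t", 5, np.ones(5) * 30, window_area_px=1000.0)
        assert nuclei.division_ratios(s, s) == (1.0, 1.0)

    def test_synthetic_k_fold_density_exact(self):
        before = NucleiStats("t0", 12, np.ones(12) * 90, window_area_px=150 * 150)
        after = NucleiStats("t1", 48, np.ones(48) * 30, window_area_px=150 * 150)
        area_ratio, density_ratio = nuclei.division_ratios(before, after)
        assert density_ratio == pytest.approx(4.0)
        assert area_ratio == pytest.approx(1 / 3)

    def test_empty_input_rejected(self):
        s = NucleiStats("t", 5, np.ones(5), window_area_px=100.0)
        empty = NucleiStats("t", 0, np.zeros(0), window_area_px=100.0)
        with pytest.raises(ConfigurationError):
            nuclei.division_ratios(s, empty)


class TestPoleCells:
    CFG = PoleCellConfig(log_range=2.0, local_range=15, log_scales=(1.5, 3.5))

    def test_empty_stack_zero_count(self):
        stack, _ = synth.generate_pole_cell_stack(0, seed=1, poisson=False, read_noise_sd=0.0)
        with pytest.warns(UserWarning):
            res = nuclei.count_pole_cells_3d(stack, 0.0, self.CFG)
        assert res.count == 0

    def test_small_cluster_counted_exactly(self):
        stack, truth = synth.generate_pole_cell_stack(8, cluster_radius=14.0, seed=2)
        res = nuclei.count_pole_cells_3d(stack, 0.0, self.CFG)
        assert abs(res.count - truth.count) <= 1

    def test_tilt_detilt_count_invariant(self):
        tilted, _ = synth.generate_pole_cell_stack(15, cluster_radius=15.0, tilt_angle=-25.0, seed=3)
        plain, _ = synth.generate_pole_cell_stack(15, cluster_radius=15.0, tilt_angle=0.0, seed=3)
        n_tilted = nuclei.count_pole_cells_3d(tilted, 25.0, self.CFG).count
        n_plain = nuclei.count_pole_cells_3d(plain, 0.0, self.CFG).count
        assert abs(n_tilted - n_plain) <= 1

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigurationError):
            PoleCellCount("DS", "TP", 0.0, -1)


class TestSummarizeCounts:
    @staticmethod
    def _counts(values):
        return [PoleCellCount("DS", f"TP{i}", 0.0, v) for i, v in enumerate(values)]

    def test_constant_counts(self):
        assert nuclei.summarize_counts(self._counts([27, 27, 27])) == (27.0, 0.0)

    def test_two_counts_closed_form(self):
        mean, sd = nuclei.summarize_counts(self._counts([25, 30]))
        assert mean == pytest.approx(27.5)
        assert sd == pytest.approx(3.5355, abs=1e-3)

    def test_single_count_rejected(self):
        with pytest.raises(ConfigurationError):
            nuclei.summarize_counts(self._counts([27]))
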