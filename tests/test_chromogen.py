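import numpy as np
import pytest

import reference
from ihcquant import (
    SegmentationParams,
    SimulationParams,
    adjust_brightness_contrast,
    count_mask,
    detect_brown,
    detect_red,
    plan_grid,
    quantify_tile,
    render_tile,
    rgb_to_ycbcr,
    shift_brown_to_red,
    split,
    threshold_to_binary,
)

RED = (200, 45, 60)  # alkaline-phosphatase red chromogen
BROWN = (120, 80, 45)  # DAB
WHITE = (255, 255, 255)


def uniform_tile(rgb, h=8, w=8):
    return np.full((h, w, 3), rgb, dtype=np.uint8)


class TestYCbCr:
    def test_achromatic_fixed_point(self):
        out = rgb_to_ycbcr(uniform_tile((128, 128, 128)))
        np.testing.assert_allclose(out, 128.0)

    def test_pure_red_saturates_cr(self):
        # Cr = 128 + 0.5*255 clips at 255
        out = rgb_to_ycbcr(uniform_tile((255, 0, 0)))
        assert out[0, 0, 2] == 255.0
        np.testing.assert_allclose(out[0, 0, 0], 0.299 * 255, atol=1e-9)

    def test_pure_blue_saturates_cb(self):
        out = rgb_to_ycbcr(uniform_tile((0, 0, 255)))
        assert out[0, 0, 1] == 255.0

    def test_matches_scalar_reference_on_random_pixels(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 256, size=(5, 7, 3), dtype=np.uint8)
        out = rgb_to_ycbcr(tile)
        for i in range(5):
            for j in range(7):
                expected = reference.ycbcr_pixel(*(float(c) for c in tile[i, j]))
                np.testing.assert_allclose(out[i, j], expected, atol=1e-9)


class TestBrightnessContrast:
    def test_identity(self):
        channel = np.arange(256, dtype=float).reshape(16, 16)
        np.testing.assert_array_equal(adjust_brightness_contrast(channel, 1.0, 0.0), channel)

    def test_midgrey_pivot_fixed_under_gain(self):
        assert adjust_brightness_contrast(np.array([[128.0]]), 2.0, 0.0)[0, 0] == 128.0

    def test_hand_computed_example(self):
        # 2*(150-128)+128+10 = 182
        assert adjust_brightness_contrast(np.array([[150.0]]), 2.0, 10.0)[0, 0] == 182.0

    def test_clipping(self):
        out = adjust_brightness_contrast(np.array([[250.0, 5.0]]), 3.0, 0.0)
        np.testing.assert_array_equal(out, [[255.0, 0.0]])

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            adjust_brightness_contrast(np.zeros((2, 2)), 0.0)


class TestThreshold:
    def test_boundary_is_strict(self):
        channel = np.full((3, 3), 200.0)
        assert threshold_to_binary(channel, 150).all()
        assert not threshold_to_binary(channel, 200).any()  # strictly greater
        assert not threshold_to_binary(channel, 255).any()

    def test_zero_threshold_catches_positive_values(self):
        assert threshold_to_binary(np.ones((2, 2)), 0).all()


class TestDetectors:
    def test_white_tile_has_no_stain(self, params):
        tile = uniform_tile(WHITE)
        assert not detect_red(tile, params).any()
        assert not detect_brown(tile, params).any()

    def test_red_chromogen_detected_brown_not(self, params):
        assert detect_red(uniform_tile(RED), params).all()
        assert not detect_red(uniform_tile(BROWN), params).any()

    def test_brown_chromogen_detected_by_second_pass(self, params):
        assert detect_brown(uniform_tile(BROWN), params).all()
        assert not detect_brown(uniform_tile(RED), params).any()

    def test_grey_pixels_unchanged_by_hue_shift(self, params):
        tile = uniform_tile((90, 90, 90))
        np.testing.assert_array_equal(shift_brown_to_red(tile, params), tile)

    def test_red_pixels_outside_brown_band_pass_through(self, params):
        tile = uniform_tile(RED)
        np.testing.assert_array_equal(shift_brown_to_red(tile, params), tile)

    def test_brown_pixels_become_red_detectable(self, params):
        shifted = shift_brown_to_red(uniform_tile(BROWN), params)
        assert detect_red(shifted, params).all()

    def test_offset_shift_mode_also_reddens_brown(self):
        # rotate brown hue (~20/255) back past red and boost brightness
        params = SegmentationParams(
            brown_shift_mode="offset", brown_shift_target=(235.0, 80.0, 120.0)
        )
        shifted = shift_brown_to_red(uniform_tile(BROWN), params)
        assert detect_red(shifted, params).all()

    def test_masks_disjoint_under_mutual_exclusion(self, params):
        half = np.concatenate([uniform_tile(RED, 8, 4), uniform_tile(BROWN, 8, 4)], axis=1)
        red = detect_red(half, params)
        brown = detect_brown(half, params)
        assert not (red & brown).any()
        assert red[:, :4].all() and brown[:, 4:].all()

    def test_exclusion_off_lets_brown_mask_cover_red(self):
        params = SegmentationParams(mutual_exclusion=False)
        tile = uniform_tile(RED)
        assert detect_brown(tile, params).all()  # red survives the shift pass


class TestCounting:
    def test_count_mask_extremes(self):
        assert count_mask(np.zeros((10, 10), bool)) == 0
        assert count_mask(np.ones((800, 1200), bool)) == 960_000

    def test_count_equals_loop_tally(self):
        rng = np.random.default_rng(1)
        mask = rng.random((30, 40)) > 0.6
        tally = sum(1 for i in range(30) for j in range(40) if mask[i, j])
        assert count_mask(mask) == tally
        assert count_mask(mask) + count_mask(~mask) == mask.size

    def test_blank_tile_quantifies_to_zero(self, params):
        pc = quantify_tile(uniform_tile(WHITE, 20, 30), params, tile_id="t0")
        assert (pc.red_pixels, pc.brown_pixels, pc.total_pixels) == (0, 0, 600)

    def test_conservation_under_exclusion(self, params, small_sim):
        tile, _ = render_tile(small_sim.with_overrides(background_mode="haematoxylin"))
        pc = quantify_tile(tile, params)
        assert pc.red_pixels + pc.brown_pixels <= pc.total_pixels


class TestAgainstSimulatorTruth:
    def test_counts_track_true_blob_areas(self, params, small_sim):
        tile, truth = render_tile(small_sim)
        pc = quantify_tile(tile, params)
        assert pc.red_pixels == pytest.approx(truth.b_area_px, rel=0.10)
        assert pc.brown_pixels == pytest.approx(truth.t_area_px, rel=0.10)

    def test_noiseless_recovery_is_exact(self, params, noiseless_sim):
        tile, truth = render_tile(noiseless_sim)
        pc = quantify_tile(tile, params)
        assert pc.red_pixels == truth.b_area_px
        assert pc.brown_pixels == truth.t_area_px

    def test_adding_red_blobs_is_monotone(self, params, noiseless_sim):
        base = quantify_tile(render_tile(noiseless_sim.with_overrides(n_b_cells=5))[0], params)
        more = quantify_tile(render_tile(noiseless_sim.with_overrides(n_b_cells=10))[0], params)
        assert more.red_pixels > base.red_pixels

    def test_correlation_with_truth_across_densities(self, params):
        """Red-pixel counts track true B-blob area over 0-1000 blobs/tile."""
        reds, truths = [], []
        for i, n in enumerate([0, 5, 20, 50, 100, 200, 400, 700, 1000]):
            sim = SimulationParams(
                tile_width=300, tile_height=200, n_b_cells=n, n_t_cells=n // 2,
                cell_radius_mean=3.0, cell_radius_sd=0.5, overlap_allowed=True,
                seed=100 + i,
            )
            tile, truth = render_tile(sim)
            reds.append(quantify_tile(tile, params).red_pixels)
            truths.append(truth.b_area_px)
        r = np.corrcoef(reds, truths)[0, 1]
        assert r >= 0.99

    def test_tiling_does_not_change_totals(self, params, small_sim):
        """Pixel classification is local: mosaic sums equal whole-image counts."""
        tile, _ = render_tile(small_sim)
        whole = quantify_tile(tile, params)
        grid = plan_grid(tile.shape[1], tile.shape[0], 64, 48)
        parts = [quantify_tile(t.pixels, params) for t in split(tile, grid)]
        assert sum(p.red_pixels for p in parts) == whole.red_pixels
        assert sum(p.brown_pixels for p in parts) == whole.brown_pixels
        assert sum(p.total_pixels for p in parts) == whole.total_pixels


class TestOracleEquivalence:
    def test_vectorised_masks_match_per_pixel_classifier(self, params, small_sim):
        sim = small_sim.with_overrides(
            tile_width=48, tile_height=32, n_b_cells=3, n_t_cells=4,
            cell_radius_mean=3.0, cell_radius_sd=0.5,
            background_mode="haematoxylin",
        )
        tile, _ = render_tile(sim)
        red, brown = detect_red(tile, params), detect_brown(tile, params)
        red_ref, brown_ref = reference.masks_by_loop(tile, params)
        np.testing.assert_array_equal(red, red_ref)
        np.testing.assert_array_equal(brown, brown_ref)


class TestParams:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "seg.yaml"
        path.write_text(
            "cr_threshold: 160\nbrown_shift_target: [0, 220, 190]\nmutual_exclusion: false\n"
        )
        params = SegmentationParams.from_yaml(path)
        assert params.cr_threshold == 160
        assert params.brown_shift_target == (0, 220, 190)
        assert not params.mutual_exclusion

    @pytest.mark.parametrize(
        "bad", [{"cr_threshold": 300}, {"contrast_gain": 0}, {"brown_shift_mode": "x"},
                {"brown_shift_target": (0, 300, 0)}]
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            SegmentationParams(**bad)
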