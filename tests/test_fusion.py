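"""Fusion rules: activity measures, dependency maps, weight maps, pipeline."""

import math

import numpy as np
import pytest

from nsctfuse import FusionConfig, GGDParams, fuse_gray_color, fuse_images
from nsctfuse.fusion import (
    DependencyField,
    WeightMap,
    effective_block_size,
    fit_band_ggds,
    fuse_high,
    fuse_low,
    horizontal_dependency,
    local_entropy,
    normalize_dependencies,
    regional_std,
    saliency_map,
    update_coefficients,
    vertical_dependency,
    weight_maps,
)
from nsctfuse.ggd_stats import jsd_ggd, sample_ggd
from nsctfuse.synthetic import make_ggd_band

LN2 = math.log(2.0)


def loop_regional_std(band, window):
    """Brute-force oracle: explicit loops, symmetric padding, uniform weights."""
    pad = window // 2
    padded = np.pad(band, pad, mode="symmetric")
    out = np.zeros_like(band, dtype=float)
    for y in range(band.shape[0]):
        for x in range(band.shape[1]):
            win = padded[y : y + window, x : x + window]
            out[y, x] = np.sqrt(np.mean((win - win.mean()) ** 2))
    return out


def loop_local_entropy(band, window, eps=1e-12):
    pad = window // 2
    padded = np.pad(band, pad, mode="symmetric")
    out = np.zeros_like(band, dtype=float)
    for y in range(band.shape[0]):
        for x in range(band.shape[1]):
            sq = padded[y : y + window, x : x + window] ** 2
            p = sq / (sq.sum() + eps)
            nz = p > 0
            out[y, x] = -np.sum(p[nz] * np.log(p[nz])) / np.log(window**2)
    return out


class TestRegionalStd:
    def test_constant_band_is_zero(self):
        np.testing.assert_array_equal(regional_std(np.full((10, 10), 4.2), 3), 0.0)

    def test_checkerboard_interior_value(self):
        # +-1 checkerboard, 3x3 window: local mean is +-1/9, so the RMS
        # deviation is sqrt(1 - 1/81) at interior pixels (loop oracle agrees)
        y, x = np.mgrid[0:12, 0:12]
        board = np.where((y + x) % 2 == 0, 1.0, -1.0)
        d = regional_std(board, 3)
        expected = math.sqrt(1.0 - 1.0 / 81.0)
        np.testing.assert_allclose(d[2:-2, 2:-2], expected, rtol=1e-12)
        np.testing.assert_allclose(d, loop_regional_std(board, 3), atol=1e-12)

    def test_matches_loop_oracle_on_random_band(self, rng):
        band = rng.standard_normal((9, 13))
        np.testing.assert_allclose(
            regional_std(band, 3), loop_regional_std(band, 3), atol=1e-10
        )

    def test_offset_invariance(self, rng):
        band = rng.standard_normal((8, 8))
        np.testing.assert_allclose(
            regional_std(band + 17.0, 3), regional_std(band, 3), atol=1e-10
        )


class TestLocalEntropy:
    def test_single_dominant_coefficient_gives_zero(self):
        band = np.zeros((7, 7))
        band[3, 3] = 5.0
        assert local_entropy(band, 3)[3, 3] == pytest.approx(0.0, abs=1e-9)

    def test_equal_magnitudes_give_one(self):
        band = np.where(np.indices((8, 8)).sum(axis=0) % 2 == 0, 2.0, -2.0)
        assert local_entropy(band, 3)[4, 4] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_window(self):
        # center window squares: (4, 4, 1, 0...): entropy of (4/9, 4/9, 1/9)
        band = np.zeros((5, 5))
        band[2, 2] = 2.0
        band[2, 1] = 2.0
        band[1, 2] = 1.0
        p = np.array([4 / 9, 4 / 9, 1 / 9])
        expected = -np.sum(p * np.log(p)) / np.log(9.0)
        assert local_entropy(band, 3)[2, 2] == pytest.approx(expected, rel=1e-9)

    def test_matches_loop_oracle(self, rng):
        band = rng.standard_normal((8, 11))
        np.testing.assert_allclose(
            local_entropy(band, 3), loop_local_entropy(band, 3), atol=1e-9
        )


class TestFuseLow:
    def test_identity_on_equal_inputs(self, rng, default_cfg):
        x = rng.random((32, 32))
        np.testing.assert_allclose(fuse_low(x, x, default_cfg), x, atol=1e-12)

    def test_textured_side_wins_where_flat(self, default_cfg):
        flat = np.full((16, 16), 0.5)
        textured = np.full((16, 16), 0.5)
        textured[8, 8] = 1.0
        fused = fuse_low(flat, textured, default_cfg)
        # at the texture pixel delta_B = 1; entropy weights stay 0.5 for the
        # flat side, so the fused value leans toward the textured input
        assert fused[8, 8] > 0.5 * (flat[8, 8] + textured[8, 8])

    def test_matches_spreadsheet_oracle(self, rng, default_cfg):
        a = rng.random((8, 8))
        b = rng.random((8, 8))
        p = default_cfg.sharpness
        da = loop_regional_std(a, 3) ** p
        db = loop_regional_std(b, 3) ** p
        ea = loop_local_entropy(a, 3)
        eb = loop_local_entropy(b, 3)
        delta_a = da / (da + db)
        xi_a = ea / (ea + eb)
        expected = 0.5 * (delta_a + xi_a) * a + 0.5 * ((1 - delta_a) + (1 - xi_a)) * b
        np.testing.assert_allclose(fuse_low(a, b, default_cfg), expected, atol=1e-9)

    def test_convexity(self, rng, default_cfg):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        fused = fuse_low(a, b, default_cfg)
        assert np.all(fused >= np.minimum(a, b) - 1e-12)
        assert np.all(fused <= np.maximum(a, b) + 1e-12)

    def test_shape_mismatch_raises(self, default_cfg):
        with pytest.raises(ValueError):
            fuse_low(np.zeros((8, 8)), np.zeros((8, 9)), default_cfg)


class TestBlockFits:
    def test_tiling_arithmetic(self):
        grid = fit_band_ggds(np.random.default_rng(0).standard_normal((256, 256)), 32)
        assert grid.grid_shape == (8, 8)

    def test_block_auto_shrinks_for_small_bands(self):
        assert effective_block_size((64, 64), 32) == 16
        assert effective_block_size((256, 256), 32) == 32

    def test_recovers_shape_within_small_sample_bounds(self):
        band = make_ggd_band(256, GGDParams(1.0, 1.5), seed=13)
        grid = fit_band_ggds(band, 32)
        assert np.all(grid.beta >= 1.2) and np.all(grid.beta <= 1.9)

    def test_all_zero_band_gets_fallback(self):
        grid = fit_band_ggds(np.zeros((64, 64)), 16, eps=1e-12)
        assert np.all(grid.alpha == 1e-12)
        assert np.all(grid.beta == 2.0)


def _noise_grid(alpha, beta, seed, size=64, block=16):
    return fit_band_ggds(make_ggd_band(size, GGDParams(alpha, beta), seed), block)


class TestDependencies:
    def test_identical_subbands_have_zero_horizontal_dependency(self):
        g = _noise_grid(1.0, 1.5, seed=1)
        scale = [g, g, g]
        np.testing.assert_array_equal(horizontal_dependency(scale, 0), 0.0)

    def test_single_band_scale_is_zero(self):
        scale = [_noise_grid(1.0, 1.5, seed=1)]
        np.testing.assert_array_equal(horizontal_dependency(scale, 0), 0.0)

    def test_disjoint_pair_approaches_ln2(self):
        scale = [_noise_grid(0.01, 2.0, seed=2), _noise_grid(100.0, 2.0, seed=3)]
        dep = horizontal_dependency(scale, 0)
        assert np.all(dep > 0.9 * LN2)

    def test_sibling_order_irrelevant(self):
        grids = [_noise_grid(a, b, seed=s) for a, b, s in
                 [(0.5, 1.0, 4), (1.0, 1.5, 5), (2.0, 2.0, 6)]]
        dep = horizontal_dependency(grids, 0)
        dep_permuted = horizontal_dependency([grids[0], grids[2], grids[1]], 0)
        np.testing.assert_allclose(dep, dep_permuted, atol=1e-14)

    def test_vertical_matches_loop_oracle_on_two_scale_pyramid(self):
        fits = [
            [_noise_grid(0.6, 1.0, seed=7), _noise_grid(1.1, 1.4, seed=8)],
            [_noise_grid(0.9, 2.0, seed=9), _noise_grid(1.7, 0.9, seed=10)],
        ]
        for l, i in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            grid_i = fits[l][i]
            gy, gx = grid_i.grid_shape
            expected_tiles = np.zeros((gy, gx))
            for neighbor in (l - 1, l + 1):
                if 0 <= neighbor < len(fits):
                    for grid_j in fits[neighbor]:
                        for iy in range(gy):
                            for ix in range(gx):
                                expected_tiles[iy, ix] += jsd_ggd(
                                    grid_i.params_at(iy, ix), grid_j.params_at(iy, ix)
                                )
            np.testing.assert_allclose(
                vertical_dependency(fits, l, i),
                grid_i.broadcast(expected_tiles),
                atol=1e-12,
            )

    def test_single_scale_pyramid_has_zero_vertical_dependency(self):
        fits = [[_noise_grid(1.0, 1.5, seed=11)]]
        np.testing.assert_array_equal(vertical_dependency(fits, 0, 0), 0.0)


class TestNormalizeAndUpdate:
    @pytest.mark.parametrize(
        "h,v,expected",
        [
            (2.0, 2.0, (0.5, 0.5)),
            (3.0, 1.0, (0.75, 0.25)),
            (0.0, 0.0, (0.0, 0.0)),
        ],
    )
    def test_normalization_cases(self, h, v, expected):
        dep = normalize_dependencies(np.full((4, 4), h), np.full((4, 4), v))
        assert dep.jsd_h[0, 0] == pytest.approx(expected[0])
        assert dep.jsd_v[0, 0] == pytest.approx(expected[1])

    def test_components_sum_to_zero_or_one(self, rng):
        dep = normalize_dependencies(rng.random((16, 16)), rng.random((16, 16)))
        total = dep.jsd_h + dep.jsd_v
        assert np.all((np.abs(total) < 1e-12) | (np.abs(total - 1.0) < 1e-12))

    @pytest.mark.parametrize(
        "h,v,mult", [(0.5, 0.5, 1.5), (1.0, 0.0, 2.0), (0.0, 0.0, 1.0)]
    )
    def test_update_multiplier(self, rng, h, v, mult):
        band = rng.standard_normal((8, 8))
        dep = DependencyField(np.full((8, 8), h), np.full((8, 8), v))
        np.testing.assert_allclose(update_coefficients(band, dep), mult * band)

    def test_update_multiplier_bounded(self, rng):
        dep = normalize_dependencies(rng.random((16, 16)), rng.random((16, 16)))
        band = np.ones((16, 16))
        updated = update_coefficients(band, dep)
        assert np.all(updated >= 1.0 - 1e-12) and np.all(updated <= 2.0 + 1e-12)


class TestSaliencyAndWeights:
    def test_constant_band_maps_to_its_magnitude(self):
        s = saliency_map(np.full((32, 32), -0.3), 5, 5.0)
        np.testing.assert_allclose(s, 0.3, atol=1e-12)

    def test_nonnegative_and_homogeneous(self, rng):
        band = rng.standard_normal((32, 32))
        s1 = saliency_map(band, 5, 5.0)
        s2 = saliency_map(-4.0 * band, 5, 5.0)
        assert np.all(s1 >= 0.0)
        np.testing.assert_allclose(s2, 4.0 * s1, atol=1e-12)

    def test_weight_maps_partition(self, rng):
        w = weight_maps(rng.random((16, 16)), rng.random((16, 16)))
        assert set(np.unique(w.w_a)) <= {0.0, 1.0}
        np.testing.assert_array_equal(w.w_a + w.w_b, 1.0)

    def test_tie_goes_to_first_image(self):
        s = np.ones((4, 4))
        w = weight_maps(s, s)
        np.testing.assert_array_equal(w.w_a, 1.0)

    def test_fuse_high_selects_a_pixel_from_one_source(self, rng):
        a = rng.standard_normal((16, 16))
        b = rng.standard_normal((16, 16))
        w = weight_maps(rng.random((16, 16)), rng.random((16, 16)))
        fused = fuse_high(a, b, w)
        assert np.all((fused == a) | (fused == b))
        np.testing.assert_array_equal(fuse_high(a, b, WeightMap(np.ones_like(a), np.zeros_like(a))), a)


class TestPipeline:
    def test_identity_on_equal_inputs(self, phantom_pair, default_cfg):
        fused = fuse_images(phantom_pair.a, phantom_pair.a, default_cfg)
        assert np.abs(fused - phantom_pair.a).max() < 1e-6

    def test_deterministic(self, phantom_pair, default_cfg, fused_phantom):
        again = fuse_images(phantom_pair.a, phantom_pair.b, default_cfg)
        np.testing.assert_array_equal(again, fused_phantom)

    def test_shape_mismatch_raises(self, default_cfg):
        with pytest.raises(ValueError):
            fuse_images(np.zeros((32, 32)), np.zeros((32, 64)), default_cfg)

    def test_non_finite_input_raises(self, default_cfg):
        bad = np.zeros((32, 32))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fuse_images(bad, np.zeros((32, 32)), default_cfg)


@pytest.fixture(scope="module")
def small_cfg():
    return FusionConfig(levels=2, directions=(2, 3), block_size=16)


class TestGrayColorFusion:
    def test_chroma_passthrough(self, phantom_pair, small_cfg):
        from skimage.color import rgb2ycbcr

        rgb = np.stack([phantom_pair.b] * 3, axis=-1) * 0.8 + 0.1
        rgb[..., 0] *= 1.1  # give it real chroma
        rgb = np.clip(rgb, 0, 1)
        fused = fuse_gray_color(phantom_pair.a, rgb, small_cfg)
        np.testing.assert_allclose(
            rgb2ycbcr(fused)[..., 1:], rgb2ycbcr(rgb)[..., 1:], atol=1.5
        )

    def test_luminance_equals_gray_fusion_for_neutral_color(
        self, phantom_pair, small_cfg
    ):
        from skimage.color import rgb2ycbcr

        rgb = np.stack([phantom_pair.b] * 3, axis=-1)
        fused_rgb = fuse_gray_color(phantom_pair.a, rgb, small_cfg)
        luma = (rgb2ycbcr(fused_rgb)[..., 0] - 16.0) / 219.0
        expected = np.clip(
            fuse_images(phantom_pair.a, phantom_pair.b, small_cfg), 0.0, 1.0
        )
        np.testing.assert_allclose(luma, expected, atol=5e-3)

    def test_colorspace_round_trip(self, rng):
        from skimage.color import rgb2ycbcr, ycbcr2rgb

        rgb = rng.random((32, 32, 3))
        back = ycbcr2rgb(rgb2ycbcr(rgb))
        assert np.abs(back - rgb).max() < 1.0 / 255.0

    def test_wrong_channel_count_raises(self, phantom_pair):
        with pytest.raises(ValueError, match="3 channels"):
            fuse_gray_color(phantom_pair.a, np.zeros(phantom_pair.a.shape + (4,)))
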