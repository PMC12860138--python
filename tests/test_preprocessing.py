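import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histoseg.imaging_io import LabelMap, RgbImage
from histoseg.preprocessing import (
    GRAY_WEIGHTS,
    AugmentConfig,
    ClaheParams,
    StainMatrix,
    apply_clahe,
    augment_pair,
    cubic_kernel,
    od_to_rgb,
    preprocess_for_model,
    resize_bicubic,
    rgb_to_od,
    stain_deconvolve,
    stain_jitter,
    to_grayscale,
)


def bicubic_reference(arr, th, tw):
    """Scalar 4×4 kernel-sum evaluation (independent of the vectorized path)."""
    h, w, c = arr.shape
    out = np.zeros((th, tw, c))
    for r in range(th):
        y = (r + 0.5) * h / th - 0.5
        by = int(np.floor(y))
        for col in range(tw):
            x = (col + 0.5) * w / tw - 0.5
            bx = int(np.floor(x))
            acc = np.zeros(c)
            for i in range(-1, 3):
                for j in range(-1, 3):
                    wy = cubic_kernel(np.array([y - (by + i)]))[0]
                    wx = cubic_kernel(np.array([x - (bx + j)]))[0]
                    yy = min(max(by + i, 0), h - 1)
                    xx = min(max(bx + j, 0), w - 1)
                    acc += arr[yy, xx] * wy * wx
            out[r, col] = acc
    return out


class TestResizeAndGray:
    def test_constant_image_stays_constant(self):
        img = RgbImage(np.full((6, 6, 3), 100, np.uint8))
        assert (resize_bicubic(img, 9, 4).pixels == 100).all()

    def test_identity_resize(self, rng):
        img = RgbImage(rng.integers(0, 256, (5, 7, 3)).astype(np.uint8))
        assert (resize_bicubic(img, 5, 7).pixels == img.pixels).all()

    def test_matches_scalar_kernel_sum(self, rng):
        arr = rng.integers(0, 256, (8, 8, 3)).astype(float)
        ours = resize_bicubic(RgbImage(arr.astype(np.uint8)), 4, 4).pixels
        ref = np.clip(np.round(bicubic_reference(arr, 4, 4)), 0, 255)
        assert (ours == ref).all()

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            resize_bicubic(RgbImage(np.zeros((4, 4, 3), np.uint8)), 0, 4)

    @pytest.mark.parametrize(
        "pixel,expected",
        [((255, 255, 255), 255.0), ((0, 0, 0), 0.0), ((255, 0, 0), 76.245)],
    )
    def test_grayscale_values(self, pixel, expected):
        img = RgbImage(np.array(pixel, np.uint8).reshape(1, 1, 3))
        assert to_grayscale(img)[0, 0] == pytest.approx(expected, abs=1e-9)

    @given(value=st.integers(0, 255))
    @settings(deadline=None, max_examples=20)
    def test_grayscale_of_constant_is_that_constant(self, value):
        # the luminance weights sum to one
        assert GRAY_WEIGHTS.sum() == pytest.approx(1.0)
        img = RgbImage(np.full((3, 3, 3), value, np.uint8))
        assert np.allclose(to_grayscale(img), value)


class TestClahe:
    def test_constant_image_maps_to_constant(self):
        out = apply_clahe(np.full((16, 16), 37.0), ClaheParams())
        assert np.allclose(out, out.flat[0])

    def test_unclipped_single_tile_equals_global_equalization(self, rng):
        from skimage import exposure

        img = rng.integers(0, 256, (32, 32)).astype(float)
        ours = apply_clahe(img, ClaheParams(clip_limit=1e9, tile_grid=(1, 1)))
        ref = exposure.equalize_hist(img.astype(np.uint8)) * 255.0
        assert np.abs(ours - ref).max() < 1e-9

    def test_tile_centres_follow_their_own_mapping(self, rng):
        # two tiles side by side: at each tile centre column the blend weight
        # of the other tile is zero, so the value equals that tile's own LUT
        left = rng.integers(0, 100, (16, 8))
        right = rng.integers(150, 256, (16, 8))
        img = np.hstack([left, right]).astype(float)
        out = apply_clahe(img, ClaheParams(clip_limit=1e9, tile_grid=(1, 2)))
        # columns outside the span of the two tile centres take their own
        # tile's mapping with no blending
        for tile, cols in ((left, (0, 3)), (right, (12, 15))):
            hist = np.bincount(tile.ravel(), minlength=256)
            lut = np.cumsum(hist) / tile.size * 255.0
            for col in cols:
                want = lut[img[:, col].astype(int)]
                assert np.abs(out[:, col] - want).max() < 1e-9

    def test_tile_grid_larger_than_image(self):
        with pytest.raises(ValueError, match="tile grid"):
            apply_clahe(np.zeros((4, 4)), ClaheParams(tile_grid=(8, 8)))


class TestOpticalDensity:
    def test_od_values(self):
        i0 = 200.0
        img = np.array([[[200, 20, 2]]], float)
        od = rgb_to_od(img, i0)
        assert np.allclose(od[0, 0], [0.0, 1.0, 2.0], atol=1e-12)

    def test_od_inverse(self):
        out = od_to_rgb(np.full((1, 1, 3), 1.0), 250.0)
        assert (out.pixels == 25).all()

    def test_round_trip_within_one_level(self, rng):
        od = rng.uniform(0, 2, (8, 8, 3))
        img = od_to_rgb(od, 240.0)
        od2 = rgb_to_od(img, 240.0)
        img2 = od_to_rgb(od2, 240.0)
        assert np.abs(img2.pixels.astype(int) - img.pixels.astype(int)).max() <= 1

    def test_nonpositive_i0(self):
        with pytest.raises(ValueError):
            rgb_to_od(np.zeros((1, 1, 3)), 0.0)


class TestStains:
    def test_basis_member_recovers_unit_concentration(self):
        stains = StainMatrix()
        od = np.broadcast_to(stains.od_vectors[0], (2, 2, 3)).copy()
        conc = stain_deconvolve(od, stains)
        assert np.allclose(conc[..., 0], 1.0, atol=1e-12)
        assert np.allclose(conc[..., 1], 0.0, atol=1e-12)

    def test_zero_od_gives_zero_concentrations(self):
        assert (stain_deconvolve(np.zeros((2, 2, 3)), StainMatrix()) == 0).all()

    def test_known_mixture_recovery(self):
        stains = StainMatrix()
        od = 0.7 * stains.od_vectors[0] + 1.3 * stains.od_vectors[1]
        conc = stain_deconvolve(np.broadcast_to(od, (3, 3, 3)).copy(), stains)
        assert np.allclose(conc, [0.7, 1.3], atol=1e-9)

    def test_dependent_stain_vectors_rejected(self):
        with pytest.raises(ValueError, match="independent"):
            StainMatrix(od_vectors=np.array([[1.0, 0, 0], [2.0, 0, 0]]))

    def test_jitter_sd_zero_is_identity(self, rng):
        img = RgbImage(rng.integers(30, 230, (8, 8, 3)).astype(np.uint8))
        out = stain_jitter(img, StainMatrix(), 0.0, seed=1)
        assert np.abs(out.pixels.astype(int) - img.pixels.astype(int)).max() <= 1

    def test_jitter_deterministic(self, rng):
        img = RgbImage(rng.integers(30, 230, (8, 8, 3)).astype(np.uint8))
        a = stain_jitter(img, StainMatrix(), 0.1, seed=9)
        b = stain_jitter(img, StainMatrix(), 0.1, seed=9)
        assert (a.pixels == b.pixels).all()

    def test_jitter_log_factors_centred(self):
        # Monte-Carlo moment check: per-stain multiplicative factors are
        # exp(N(0, sd²)), so the mean log-factor over seeds is ~0
        sd = 0.1
        n = 500
        logs = []
        for seed in range(n):
            r = np.random.default_rng(seed)
            logs.append(np.log(np.exp(r.normal(0.0, sd, size=2))))
        logs = np.array(logs)
        se = sd / np.sqrt(n)
        assert np.abs(logs.mean(axis=0)).max() < 3 * se


class TestAugment:
    def _pair(self, rng, size=12):
        img = RgbImage(rng.integers(0, 256, (size, size, 3)).astype(np.uint8))
        mask = LabelMap((rng.random((size, size)) < 0.3).astype(np.uint8))
        return img, mask

    def test_disabled_config_is_identity(self, rng):
        img, mask = self._pair(rng)
        out_img, out_mask = augment_pair(img, mask, AugmentConfig.disabled(), seed=5)
        assert (out_img.pixels == img.pixels).all()
        assert (out_mask.labels == mask.labels).all()

    def test_rotation_moves_image_and_mask_identically(self, rng):
        img, mask = self._pair(rng)
        config = AugmentConfig.disabled()
        config.rotation_choices = (90,)
        out_img, out_mask = augment_pair(img, mask, config, seed=0)
        assert (out_img.pixels == np.rot90(img.pixels)).all()
        assert (out_mask.labels == np.rot90(mask.labels)).all()

    def test_deterministic_given_seed(self, rng):
        img, mask = self._pair(rng, size=16)
        a = augment_pair(img, mask, AugmentConfig(), seed=3)
        b = augment_pair(img, mask, AugmentConfig(), seed=3)
        assert (a[0].pixels == b[0].pixels).all()
        assert (a[1].labels == b[1].labels).all()

    def test_output_dims_preserved_and_mask_binary(self, rng):
        img, mask = self._pair(rng, size=20)
        for seed in range(5):
            out_img, out_mask = augment_pair(img, mask, AugmentConfig(), seed=seed)
            assert out_img.pixels.shape == img.pixels.shape
            assert set(np.unique(out_mask.labels)) <= {0, 1}

    def test_mismatched_dims_rejected(self, rng):
        img = RgbImage(rng.integers(0, 256, (8, 8, 3)).astype(np.uint8))
        mask = LabelMap(np.zeros((9, 9), np.uint8))
        with pytest.raises(ValueError):
            augment_pair(img, mask, AugmentConfig(), seed=0)


class TestModelPipeline:
    def test_output_standardized_224(self, rng):
        img = RgbImage(rng.integers(0, 256, (96, 80, 3)).astype(np.uint8))
        out = preprocess_for_model(img)
        assert out.shape == (224, 224, 3)
        assert np.abs(out.mean(axis=(0, 1))).max() < 1e-6
        assert np.abs(out.std(axis=(0, 1)) - 1).max() < 1e-6

    def test_constant_input_maps_to_zeros(self):
        img = RgbImage(np.full((64, 64, 3), 200, np.uint8))
        out = preprocess_for_model(img, size=64)
        assert np.allclose(out, 0.0)
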