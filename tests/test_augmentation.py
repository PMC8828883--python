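"""Identities, group properties and moment bounds of the augmentation suite."""

import numpy as np
import pytest

from crcscreen.augmentation import (
    AugmentationConfig,
    StainModel,
    add_gaussian_noise,
    adjust_brightness,
    adjust_contrast,
    augment,
    gaussian_blur,
    he_color_augment,
    he_to_rgb,
    mirror,
    rgb_to_he,
    rotate,
)
from crcscreen.errors import ConfigError, ParameterError


@pytest.fixture()
def raster(rng):
    return rng.uniform(0.05, 0.95, size=(30, 40, 3))


class TestGeometric:
    def test_rotate_identity_and_group(self, raster):
        assert np.array_equal(rotate(raster, 0), raster)
        out = raster
        for _ in range(4):
            out = rotate(out, 90)
        assert np.array_equal(out, raster)
        assert np.array_equal(rotate(rotate(raster, 90), 180), rotate(raster, 270))

    def test_rotate_90_coordinate_map(self, rng):
        """Clockwise 90: source (y, x) lands at (x, H-1-y); brute-force check."""
        h, w = 3, 5
        src = rng.uniform(size=(h, w, 3))
        out = rotate(src, 90)
        assert out.shape == (w, h, 3)
        for y in range(h):
            for x in range(w):
                assert np.array_equal(out[x, h - 1 - y], src[y, x])
        # the 2x1 picture: [[a, b]] -> column [[a], [b]]
        ab = np.array([[[0.1] * 3, [0.9] * 3]])
        assert np.array_equal(rotate(ab, 90), np.array([[[0.1] * 3], [[0.9] * 3]]))

    def test_rotate_rejects_other_angles(self, raster):
        with pytest.raises(ParameterError):
            rotate(raster, 45)

    @pytest.mark.parametrize("axis", ["horizontal", "vertical"])
    def test_mirror_involution(self, raster, axis):
        assert np.array_equal(mirror(mirror(raster, axis), axis), raster)

    def test_mirror_definitions(self):
        ab = np.array([[[0.1] * 3, [0.9] * 3]])
        assert np.array_equal(mirror(ab, "horizontal"), ab[:, ::-1])
        assert np.array_equal(mirror(ab, "none"), ab)
        with pytest.raises(ParameterError):
            mirror(ab, "diagonal")

    @pytest.mark.parametrize("op", [lambda r: rotate(r, 90), lambda r: rotate(r, 270),
                                    lambda r: mirror(r, "horizontal"),
                                    lambda r: mirror(r, "vertical")])
    def test_geometric_ops_are_pixel_permutations(self, raster, op):
        out = op(raster)
        assert np.array_equal(np.sort(out.ravel()), np.sort(raster.ravel()))


class TestPhotometric:
    def test_contrast_identity_and_constant_image(self, raster):
        assert np.allclose(adjust_contrast(raster, 1.0), raster)
        const = np.full((5, 5, 3), 0.4)
        assert np.allclose(adjust_contrast(const, 1.3), const)

    def test_contrast_arithmetic(self):
        # pixels {0.2, 0.6}, mean 0.4, factor 1.3 -> {0.14, 0.66}
        img = np.array([[[0.2] * 3, [0.6] * 3]])
        out = adjust_contrast(img, 1.3)
        assert np.allclose(out, np.array([[[0.14] * 3, [0.66] * 3]]))

    def test_brightness_scaling_and_clipping(self):
        img = np.array([[[1.0, 0.9, 0.5]]])
        assert np.allclose(adjust_brightness(img, 0.7), [[[0.7, 0.63, 0.35]]])
        assert np.allclose(adjust_brightness(img, 1.3)[0, 0, :2], [1.0, 1.0])

    def test_non_positive_factors_rejected(self, raster):
        with pytest.raises(ParameterError):
            adjust_contrast(raster, 0.0)
        with pytest.raises(ParameterError):
            adjust_brightness(raster, -1.0)


class TestStainSpace:
    def test_background_maps_to_zero_concentration(self):
        white = np.full((4, 4, 3), 1.0)
        conc = rgb_to_he(white)
        assert np.abs(conc).max() < 1e-5

    def test_round_trip_within_one_gray_level(self, raster):
        back = he_to_rgb(rgb_to_he(raster))
        assert np.abs(back - raster).max() <= 1.0 / 255.0

    def test_forward_model_concentration_recovery(self):
        """Pixels synthesized from known (cH, cE) recover them to 1e-6."""
        stain = StainModel()
        conc = np.zeros((2, 2, 3))
        conc[..., 0] = [[0.3, 0.7], [0.05, 1.2]]
        conc[..., 1] = [[0.2, 0.4], [0.9, 0.01]]
        recovered = rgb_to_he(he_to_rgb(conc, stain), stain)
        assert np.abs(recovered - conc).max() < 1e-6

    def test_degenerate_stain_basis_rejected(self):
        with pytest.raises(ConfigError):
            StainModel(hematoxylin=(1, 0, 0), eosin=(2, 0, 0)).basis()

    def test_he_augment_zero_delta_is_round_trip(self, raster):
        out = he_color_augment(raster, 0.0, 0.0)
        assert np.abs(out - raster).max() <= 1.0 / 255.0

    def test_he_augment_shifts_concentration_exactly(self):
        stain = StainModel()
        conc = np.zeros((3, 3, 3))
        conc[..., 0] = 0.5
        conc[..., 1] = 0.3
        pix = he_to_rgb(conc, stain)
        shifted = rgb_to_he(he_color_augment(pix, 0.05, -0.02, stain), stain)
        assert np.allclose(shifted[..., 0], 0.55, atol=1e-4)
        assert np.allclose(shifted[..., 1], 0.28, atol=1e-4)

    def test_white_background_stays_white_under_negative_delta(self):
        white = np.full((4, 4, 3), 1.0)
        for dh, de in [(-0.05, -0.05), (0.0, -0.03), (-0.01, 0.0)]:
            out = he_color_augment(white, dh, de)
            assert np.abs(out - 1.0).max() <= 1.0 / 255.0

    def test_delta_out_of_range_rejected(self, raster):
        with pytest.raises(ParameterError):
            he_color_augment(raster, 0.06, 0.0)


class TestNoiseAndBlur:
    def test_zero_sigma_and_zero_radius_are_identity(self, raster, rng):
        assert np.array_equal(add_gaussian_noise(raster, 0.0, rng), raster)
        assert np.array_equal(gaussian_blur(raster, 0.0), raster)

    def test_noise_moments_on_full_tile(self, rng):
        """Perturbation mean within +-0.002 and std within [0.095, 0.105]."""
        gray = np.full((522, 775, 3), 0.5)
        noisy = add_gaussian_noise(gray, 0.1, rng)
        delta = noisy - gray
        assert abs(delta.mean()) < 0.002
        assert 0.095 < delta.std() < 0.105

    def test_blur_preserves_constant_images(self):
        const = np.full((20, 20, 3), 0.3)
        assert np.allclose(gaussian_blur(const, 1.5), const)

    def test_blur_conserves_mass_of_point_source(self):
        img = np.zeros((41, 41, 3))
        img[20, 20] = 0.8
        out = gaussian_blur(img, 2.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_blur_near_edge_conserves_mass(self):
        img = np.zeros((31, 31, 3))
        img[1, 2] = 0.6
        out = gaussian_blur(img, 3.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)


class TestJointPipeline:
    def test_degenerate_config_is_identity(self, raster):
        out = augment(raster, AugmentationConfig.identity(), np.random.default_rng(0))
        assert np.array_equal(out, raster)

    def test_seeded_determinism(self, raster):
        cfg = AugmentationConfig()
        a = augment(raster, cfg, np.random.default_rng(99))
        b = augment(raster, cfg, np.random.default_rng(99))
        assert np.array_equal(a, b)
        c = augment(raster, cfg, np.random.default_rng(100))
        assert not np.array_equal(a, c)

    def test_output_range_and_shape_family(self, raster, rng):
        for _ in range(5):
            out = augment(raster, AugmentationConfig(), rng)
            assert out.min() >= 0.0 and out.max() <= 1.0
            assert sorted(out.shape[:2]) == sorted(raster.shape[:2])

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            AugmentationConfig(contrast_range=(1.3, 0.7))
        with pytest.raises(ConfigError):
            AugmentationConfig(noise_sigma=-0.1)
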