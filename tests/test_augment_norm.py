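"""Normalization contract and augmentation bounds/statistics."""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from capnet.augment import (
    AugmentConfig,
    add_awgn,
    apply_tf_augment,
    crop_resize_time,
    fit_norm_stats,
    gaussian_blur,
    normalize,
    random_time_shift,
    spec_augment,
)


def _images_with_stds(stds, shape=(8, 8)):
    """Images with exactly the requested pixel standard deviations."""
    base = np.resize([-1.0, 1.0], shape)  # mean 0, std exactly 1
    return np.stack([s * base for s in stds])


class TestNormStats:
    def test_constant_sigma_case(self):
        stats = fit_norm_stats(_images_with_stds([2.0, 2.0, 2.0]))
        assert stats.sigma_bar == pytest.approx(2.0)

    def test_arithmetic_mean_of_sigmas(self):
        stats = fit_norm_stats(_images_with_stds([1.0, 3.0]))
        assert stats.sigma_bar == pytest.approx(2.0)

    def test_matches_brute_force_on_random_images(self, rng):
        imgs = rng.standard_normal((100, 6, 9))
        stats = fit_norm_stats(imgs)
        brute = np.mean([im.std() for im in imgs])
        assert abs(stats.sigma_bar - brute) < 1e-9

    def test_all_constant_set_rejected(self):
        with pytest.raises(ValueError, match="sigma_bar"):
            fit_norm_stats(np.ones((5, 4, 4)))


class TestNormalize:
    def test_constant_image_maps_to_zero(self):
        stats = fit_norm_stats(_images_with_stds([1.0]))
        assert np.all(normalize(np.full((4, 4), 7.0), stats) == 0)

    def test_unit_std_fixed_point(self):
        imgs = _images_with_stds([2.0, 2.0])
        stats = fit_norm_stats(imgs)
        out = normalize(imgs[0], stats)
        assert out.std() == pytest.approx(1.0)
        assert out.mean() == pytest.approx(0.0, abs=1e-7)

    def test_contrast_ratio_preserved(self):
        """Std ratios survive the shared-scale normalization (the reason for
        not standardizing per image)."""
        imgs = _images_with_stds([1.0, 2.0])
        stats = fit_norm_stats(imgs)
        a, b = normalize(imgs[0], stats), normalize(imgs[1], stats)
        assert a.std() / b.std() == pytest.approx(0.5)

    def test_reduces_to_per_image_standardization_when_stds_equal(self, rng):
        img = rng.standard_normal((6, 6))
        stats = fit_norm_stats(np.stack([img, img[::-1]]))
        out = normalize(img, stats)
        classic = (img - img.mean()) / img.std()
        assert np.allclose(out, classic, atol=1e-6)

    def test_energy_contrast_separates_synthetic_classes(self):
        """A-phase TFR images keep a higher-variance signature than B after
        normalization (two-sample KS on per-image stds)."""
        from capnet.pipeline import prepare_dataset
        from capnet.simulate import SimConfig, generate_record

        rec = generate_record(SimConfig(duration_s=600, a_fraction=0.3, seed=21))
        data = prepare_dataset(rec, 1, "SPWVD", balance_seed=5)
        stats = fit_norm_stats(data["train_X"])
        stds = np.array([normalize(im, stats).std() for im in data["train_X"]])
        a = stds[data["train_y"] == 1]
        b = stds[data["train_y"] == 0]
        assert min(len(a), len(b)) >= 50
        assert ks_2samp(a, b).pvalue < 0.01


class TestTimeShift:
    def test_zero_margin_is_identity(self, rng):
        img = rng.standard_normal((4, 10))
        assert np.array_equal(random_time_shift(img, 10, rng), img)

    def test_boundary_offsets(self):
        img = np.arange(20, dtype=float).reshape(1, 20)

        class Fixed:
            def __init__(self, v):
                self.v = v

            def integers(self, lo, hi):
                return np.clip(self.v, lo, hi - 1)

        assert np.array_equal(random_time_shift(img, 8, Fixed(0)), img[:, :8])
        assert np.array_equal(random_time_shift(img, 8, Fixed(99)), img[:, 12:])

    def test_offsets_uniform(self, rng):
        img = np.zeros((2, 64 + 36))
        img[0] = np.arange(100)
        counts = np.zeros(65)
        for _ in range(1300):
            out = random_time_shift(img, 36, rng)
            counts[int(out[0, 0])] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_narrow_source_rejected(self, rng):
        with pytest.raises(ValueError, match="extended width"):
            random_time_shift(np.zeros((2, 5)), 10, rng)


class TestAWGN:
    def test_zero_range_is_identity(self, rng):
        img = rng.standard_normal((5, 5)).astype(np.float32)
        assert np.array_equal(add_awgn(img, (0.0, 0.0), rng), img)

    def test_std_recovered(self, rng):
        out = add_awgn(np.zeros((300, 300), dtype=np.float64), (0.7, 0.7), rng)
        assert out.std() == pytest.approx(0.7, rel=0.05)
        assert abs(out.mean()) < 0.05


class TestBlur:
    def test_prob_zero_identity(self, rng):
        img = rng.standard_normal((6, 6)).astype(np.float32)
        assert np.array_equal(gaussian_blur(img, rng, prob=0.0), img)

    def test_impulse_response_is_normalized_kernel(self, rng):
        img = np.zeros((21, 21), dtype=np.float64)
        img[10, 10] = 1.0
        out = gaussian_blur(img, rng, prob=1.0, sigma_range=(1.0, 1.0))
        assert out.sum() == pytest.approx(1.0, abs=1e-6)  # normalized kernel
        assert out[10, 10] == out.max()
        assert np.allclose(out, out[::-1, ::-1], atol=1e-12)  # symmetric

    def test_application_rate_near_half(self, rng):
        img = np.ones((3, 3), dtype=np.float32)
        applied = sum(
            not np.array_equal(gaussian_blur(img * (i + 1), rng), img * (i + 1))
            for i in range(10000)
        )
        assert 0.48 <= applied / 10000 <= 0.52


class TestSpecAugment:
    def test_zero_fractions_identity(self, rng):
        img = rng.standard_normal((10, 10)).astype(np.float32)
        out = spec_augment(img, rng, time_mask_max_frac=0.0, freq_mask_max_frac=0.0)
        assert np.array_equal(out, img)

    def test_mask_width_bounds(self, rng):
        img = rng.standard_normal((100, 288)).astype(np.float64) + 10.0
        for _ in range(200):
            out = spec_augment(img, rng)
            changed_cols = np.flatnonzero((out != img).all(axis=0))
            changed_rows = np.flatnonzero((out != img).all(axis=1))
            assert len(changed_cols) <= int(np.ceil(0.05 * 288))  # 15
            assert len(changed_rows) <= int(np.ceil(0.03 * 100))  # 3

    def test_masked_pixel_accounting(self):
        img = np.arange(100.0 * 40).reshape(100, 40)

        class Seq:
            def __init__(self, vals):
                self.vals = list(vals)

            def integers(self, lo, hi):
                v = self.vals.pop(0)
                assert lo <= v < hi, "scripted draw outside the valid range"
                return v

        # time width 2 (max ceil(0.05*40)=2) at col 3;
        # freq height 1 (max ceil(0.03*100)=3) at row 2
        out = spec_augment(img, Seq([2, 3, 1, 2]))
        changed = np.sum(out != img)
        expected = 2 * 100 + 1 * 40 - 2 * 1  # band areas minus overlap
        assert changed == expected
        assert np.all(out[:, 3:5] == img.mean())
        assert np.all(out[2, :] == img.mean())


class TestCropResize:
    def test_zero_fraction_identity(self, rng):
        img = rng.standard_normal((6, 30)).astype(np.float32)
        assert np.array_equal(crop_resize_time(img, 0.0, rng), img)

    def test_shape_always_preserved(self, rng):
        img = rng.standard_normal((7, 50)).astype(np.float32)
        for _ in range(20):
            out = crop_resize_time(img, 0.3, rng)
            assert out.shape == img.shape and out.dtype == img.dtype

    def test_ridge_coordinate_mapping(self):
        n_time = 200
        img = np.zeros((3, n_time))
        j = 120
        img[:, j] = 1.0

        class Seq:
            def __init__(self, uni, ints):
                self.uni, self.ints = uni, list(ints)

            def uniform(self, lo, hi):
                return self.uni

            def integers(self, lo, hi):
                return np.clip(self.ints.pop(0), lo, hi - 1)

        crop_frac = 0.1  # 20 columns total, all leading
        out = crop_resize_time(img, 0.1, Seq(crop_frac, [20]))
        expected = (j - 20) * (n_time - 1) / (n_time - 20 - 1)
        ridge = out[0].argmax()
        assert abs(ridge - expected) <= 1.0


class TestChain:
    def test_shape_dtype_preserved_and_reproducible(self):
        cfg = AugmentConfig()
        img = np.random.default_rng(0).standard_normal((64, 160)).astype(np.float32)
        out1 = apply_tf_augment(img, cfg, np.random.default_rng(55))
        out2 = apply_tf_augment(img, cfg, np.random.default_rng(55))
        assert out1.shape == img.shape and out1.dtype == img.dtype
        assert np.array_equal(out1, out2)
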