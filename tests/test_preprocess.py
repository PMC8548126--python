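"""The four-step photometric normalization chain and its statistics."""

import numpy as np
import pytest

from lasermark.fundus_io import FundusSample
from lasermark.preprocess import (
    NormStats,
    clahe_gamma,
    fit_norm_stats,
    minmax_rescale,
    preprocess_image,
    resize_to_canonical,
    standardize,
)


def _sample(rng, side=40, sid="s"):
    img = rng.integers(0, 256, (side, side, 3), dtype=np.uint8)
    mask = (rng.random((side, side)) > 0.8).astype(np.uint8)
    return FundusSample(id=sid, image=img, lesion_mask=mask)


class TestResize:
    def test_downscale_shape(self, rng):
        out = resize_to_canonical(_sample(rng, side=64), side=32)
        assert out.image.shape == (32, 32, 3)
        assert out.lesion_mask.shape == (32, 32)

    def test_identity_when_already_canonical(self, rng):
        s = _sample(rng, side=32)
        out = resize_to_canonical(s, side=32)
        np.testing.assert_array_equal(out.image, s.image)

    def test_masks_stay_binary(self, rng):
        out = resize_to_canonical(_sample(rng, side=50), side=37)
        assert set(np.unique(out.lesion_mask)) <= {0, 1}

    def test_macula_center_rescaled(self, rng):
        s = _sample(rng, side=64)
        s.macula_center = (32.0, 16.0)
        out = resize_to_canonical(s, side=32)
        assert out.macula_center == (16.0, 8.0)


class TestFitNormStats:
    def test_two_point_population_sd(self):
        a = np.full((4, 4, 3), 10, dtype=np.uint8)
        b = np.full((4, 4, 3), 20, dtype=np.uint8)
        stats = fit_norm_stats([a, b])
        assert np.allclose(stats.mu, 15.0)
        assert np.allclose(stats.sigma, 5.0)  # divide-by-N convention

    def test_identical_images_zero_sigma(self):
        a = np.full((4, 4, 3), 42, dtype=np.uint8)
        stats = fit_norm_stats([a, a.copy()])
        assert np.allclose(stats.sigma, 0.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        images = [rng.integers(0, 256, (8, 8, 3), dtype=np.uint8) for _ in range(4)]
        stats = fit_norm_stats(images)
        n = len(images)
        for j in range(8):
            for jj in range(8):
                for k in range(3):
                    vals = [float(img[j, jj, k]) for img in images]
                    mu = sum(vals) / n
                    sd = (sum((v - mu) ** 2 for v in vals) / n) ** 0.5
                    assert abs(stats.mu[j, jj, k] - mu) < 1e-9
                    assert abs(stats.sigma[j, jj, k] - sd) < 1e-9

    def test_requires_two_images(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_norm_stats([np.zeros((4, 4, 3), dtype=np.uint8)])


class TestStandardize:
    def test_zscore_arithmetic(self):
        stats = NormStats(mu=np.full((1, 1, 3), 15.0), sigma=np.full((1, 1, 3), 5.0),
                          n_images=2, side=1)
        z = standardize(np.full((1, 1, 3), 20.0), stats)
        assert np.allclose(z, 1.0)

    def test_zero_sigma_maps_to_zero(self):
        stats = NormStats(mu=np.full((1, 1, 3), 7.0), sigma=np.zeros((1, 1, 3)),
                          n_images=2, side=1)
        assert np.allclose(standardize(np.full((1, 1, 3), 99.0), stats), 0.0)

    def test_moment_property_over_training_set(self, rng):
        """Post-standardization per-position mean ~0 and SD ~1 where sigma > 0."""
        images = [rng.integers(0, 256, (8, 8, 3)).astype(np.uint8) for _ in range(6)]
        stats = fit_norm_stats(images)
        zs = np.stack([standardize(img.astype(float), stats) for img in images])
        ok = stats.sigma > 0
        assert np.abs(zs.mean(axis=0)[ok]).max() < 1e-6
        assert np.abs(zs.std(axis=0)[ok] - 1.0).max() < 1e-6


class TestMinmaxRescale:
    def test_linear_map_endpoints(self):
        z = np.array([-1.0, 0.0, 1.0]).reshape(3, 1, 1).repeat(3, axis=2)
        v = minmax_rescale(z)
        assert np.allclose(sorted(v[:, 0, 0]), [0.0, 127.5, 255.0])

    def test_constant_channel_maps_to_zero(self):
        z = np.full((4, 4, 3), 3.3)
        assert np.allclose(minmax_rescale(z), 0.0)

    def test_output_spans_full_range(self, rng):
        v = minmax_rescale(rng.standard_normal((8, 8, 3)))
        for k in range(3):
            assert v[..., k].min() == 0.0
            assert v[..., k].max() == 255.0


class TestClaheGamma:
    def test_gamma_fixed_points(self):
        v = np.array([[0.0, 255.0]])[..., None].repeat(3, axis=2)
        out = clahe_gamma(v, apply_clahe=False)
        assert np.allclose(out[0, 0], 0.0)
        assert np.allclose(out[0, 1], 255.0)

    def test_gamma_closed_form_midpoint(self):
        v = np.full((2, 2, 3), 127.5)
        out = clahe_gamma(v, apply_clahe=False)
        expected = 255.0 * 0.5 ** (1 / 1.2)
        assert np.allclose(out, expected, atol=1e-9)

    def test_output_clamped(self, rng):
        v = rng.uniform(0, 255, (32, 32, 3))
        out = clahe_gamma(v)
        assert out.min() >= 0.0 and out.max() <= 255.0


class TestPreprocessImage:
    def _stats(self, rng, side=48):
        imgs = [rng.integers(0, 256, (side, side, 3), dtype=np.uint8) for _ in range(3)]
        return fit_norm_stats(imgs)

    def test_output_in_unit_interval(self, rng):
        stats = self._stats(rng)
        out = preprocess_image(_sample(rng, side=48), stats)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_channel_permutation_equivariance(self, rng):
        stats = self._stats(rng)
        s = _sample(rng, side=48)
        perm = [2, 0, 1]
        s_perm = FundusSample(id="p", image=s.image[..., perm],
                              lesion_mask=s.lesion_mask)
        stats_perm = NormStats(mu=stats.mu[..., perm], sigma=stats.sigma[..., perm],
                               n_images=stats.n_images, side=stats.side)
        a = preprocess_image(s, stats).values
        b = preprocess_image(s_perm, stats_perm).values
        np.testing.assert_allclose(b, a[..., perm], atol=1e-12)

    def test_train_stats_differ_from_own_stats(self, rng):
        """Frozen training statistics must be used, not per-image statistics."""
        stats_train = self._stats(rng)
        s = _sample(rng, side=48)
        stats_own = fit_norm_stats([s.image, s.image.copy()])
        # sigma of identical pair is 0 -> standardize degenerates; use a
        # perturbed partner so both stats objects are non-degenerate
        partner = np.clip(s.image.astype(int) + 7, 0, 255).astype(np.uint8)
        stats_own = fit_norm_stats([s.image, partner])
        a = preprocess_image(s, stats_train).values
        b = preprocess_image(s, stats_own).values
        assert not np.allclose(a, b)

    def test_deterministic(self, rng):
        stats = self._stats(rng)
        s = _sample(rng, side=48)
        a = preprocess_image(s, stats).values
        b = preprocess_image(s, stats).values
        np.testing.assert_array_equal(a, b)

    def test_black_exterior_stays_zero(self, rng):
        stats = self._stats(rng)
        img = rng.integers(1, 256, (48, 48, 3), dtype=np.uint8)
        img[:10, :10] = 0  # simulated field-of-view exterior
        s = FundusSample(id="b", image=img, lesion_mask=np.zeros((48, 48), np.uint8))
        out = preprocess_image(s, stats).values
        assert np.all(out[:10, :10] == 0.0)


def test_norm_stats_hdf5_roundtrip(tmp_path, rng):
    imgs = [rng.integers(0, 256, (8, 8, 3), dtype=np.uint8) for _ in range(3)]
    stats = fit_norm_stats(imgs)
    stats.save(tmp_path / "stats.h5")
    back = NormStats.load(tmp_path / "stats.h5")
    np.testing.assert_array_equal(back.mu, stats.mu)
    np.testing.assert_array_equal(back.sigma, stats.sigma)
    assert back.n_images == 3 and back.side == 8
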