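"""Quality metrics against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from scipy import stats as scipy_stats
from skimage.metrics import structural_similarity

import partialscan as ps
from partialscan.errors import DimensionError, MetricError, ParameterError


@pytest.fixture
def random_pairs(rng):
    pairs = []
    for _ in range(20):
        a = rng.random((64, 64))
        b = np.clip(a + rng.normal(0, 0.08, (64, 64)), 0, 1)
        pairs.append((a, b))
    return pairs


class TestMSE:
    def test_identity_and_closed_form(self):
        assert ps.mse(np.zeros((2, 2)), np.zeros((2, 2))) == 0.0
        assert ps.mse(np.zeros((2, 2)), np.ones((2, 2))) == 1.0

    def test_brute_force_oracle(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        acc = 0.0
        for i in range(16):
            for j in range(16):
                acc += (a[i, j] - b[i, j]) ** 2
        assert abs(ps.mse(a, b) - acc / 256) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            ps.mse(np.zeros((2, 2)), np.zeros((3, 2)))


class TestPSNR:
    def test_closed_forms(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)  # mse = 0.01
        assert abs(ps.psnr(a, b) - 20.0) < 1e-12
        assert abs(ps.psnr(a, np.ones((10, 10)))) < 1e-12  # mse 1 -> 0 dB

    def test_identity_sentinel(self):
        assert ps.psnr(np.ones((4, 4)), np.ones((4, 4))) == math.inf

    def test_monotone_decreasing_in_mse(self, rng):
        a = rng.random((32, 32))
        noisy = [np.clip(a + rng.normal(0, s, a.shape), 0, 1)
                 for s in (0.01, 0.05, 0.2)]
        psnrs = [ps.psnr(a, b) for b in noisy]
        assert psnrs[0] > psnrs[1] > psnrs[2]


class TestSSIM:
    def test_self_similarity(self, rng):
        a = rng.random((32, 32))
        assert ps.ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_checkerboard_negative(self):
        a = np.indices((32, 32)).sum(axis=0) % 2 * 1.0
        assert ps.ssim(a, 1 - a) < 0

    def test_agrees_with_skimage(self, random_pairs):
        for a, b in random_pairs:
            ref = structural_similarity(a, b, win_size=7, data_range=1.0)
            assert abs(ps.ssim(a, b, window=7) - ref) < 1e-6

    def test_window_larger_than_image(self):
        with pytest.raises(ParameterError):
            ps.ssim(np.zeros((5, 5)), np.zeros((5, 5)), window=7)


class TestPearson:
    def test_trivial_cases(self, rng):
        a = rng.random((16, 16))
        assert ps.pearson(a, a) == pytest.approx(1.0, abs=1e-12)
        assert ps.pearson(a, 2.0 - a) == pytest.approx(-1.0, abs=1e-12)

    def test_agrees_with_scipy(self, random_pairs):
        for a, b in random_pairs:
            ref = scipy_stats.pearsonr(a.ravel(), b.ravel())[0]
            assert abs(ps.pearson(a, b) - ref) < 1e-12

    def test_constant_image_undefined(self):
        with pytest.raises(MetricError):
            ps.pearson(np.ones((4, 4)), np.zeros((4, 4)) + np.arange(4))


class TestEdgeDensity:
    def test_constant_image_zero(self):
        assert ps.edge_density(np.full((32, 32), 0.5)) == 0.0

    def test_single_step_edge(self):
        img = np.zeros((100, 100))
        img[50:, :] = 1.0
        d = ps.edge_density(img)
        assert 0.005 <= d <= 0.02  # ~one 100-pixel edge, within 2x for thinning

    def test_blur_reduces_density(self, rng):
        from scipy.ndimage import gaussian_filter

        fine = (np.indices((64, 64)).sum(axis=0) % 8 < 4).astype(float)
        blurred = gaussian_filter(fine, 6.0)
        assert ps.edge_density(fine) > ps.edge_density(blurred)

    def test_offset_invariance(self, rng):
        a = rng.random((32, 32)) * 0.5
        assert ps.edge_density(a) == ps.edge_density(a + 0.25)


class TestFrequencyRatio:
    def test_identity(self, rng):
        a = rng.random((32, 32))
        assert ps.frequency_ratio(a, a) == pytest.approx(1.0)

    def test_blur_below_one_noise_above_one(self, rng):
        from scipy.ndimage import gaussian_filter

        a = rng.random((64, 64))
        assert ps.frequency_ratio(gaussian_filter(a, 2.0), a) < 1.0
        noisy = a + rng.normal(0, 0.3, a.shape)
        assert ps.frequency_ratio(noisy, a) > 1.0

    def test_constant_original_undefined(self, rng):
        with pytest.raises(MetricError):
            ps.frequency_ratio(rng.random((8, 8)), np.ones((8, 8)))


class TestEvaluatePair:
    def test_identity_panel(self, small_scene):
        rep = ps.evaluate_pair(small_scene, small_scene)
        assert rep.mse == 0 and rep.ssim == pytest.approx(1.0)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.freq_ratio == pytest.approx(1.0)
        assert rep.psnr == math.inf

    def test_batch_of_identical_pairs_has_zero_sd(self, small_scene):
        rep = ps.evaluate_pairs([(small_scene, small_scene)] * 3)
        assert rep.n_images == 3
        assert all(v == 0.0 for v in rep.sd.values())

    def test_batch_means_equal_per_pair_means(self, rng):
        pairs = [(rng.random((32, 32)), rng.random((32, 32))) for _ in range(3)]
        batch = ps.evaluate_pairs(pairs)
        singles = [ps.evaluate_pair(o, r) for o, r in pairs]
        assert batch.mse == pytest.approx(np.mean([s.mse for s in singles]))
        assert batch.ssim == pytest.approx(np.mean([s.ssim for s in singles]))
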