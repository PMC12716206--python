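"""Inpainting models: partial-conv contract, loss, baselines, training smoke."""

import numpy as np
import pytest

import partialscan as ps
from partialscan import autodiff as ad
from partialscan.errors import (ConfigurationError, CorrectionError,
                                DimensionError, ParameterError)
from partialscan.heightmap import MaskRaster
from partialscan.models import loss_graph

SMALL = dict(filters=(4, 8), input_size=(32, 32))


class TestPartialConvPrimitive:
    def test_all_valid_equals_plain_convolution(self, rng):
        v = rng.normal(size=(3, 3))
        k = rng.normal(size=(3, 3))
        out, bit = ps.partial_conv(v, np.ones((3, 3)), k, bias=0.7)
        assert bit == 1
        assert out == pytest.approx((v * k).sum() + 0.7, abs=1e-12)

    def test_all_invalid_hole_rule(self, rng):
        out, bit = ps.partial_conv(rng.normal(size=(3, 3)), np.zeros((3, 3)),
                                   rng.normal(size=(3, 3)), bias=0.5)
        assert (out, bit) == (0.0, 0)

    def test_three_valid_pixels_hand_computation(self, rng):
        v = rng.normal(size=(3, 3))
        k = rng.normal(size=(3, 3))
        m = np.zeros((3, 3))
        m[0, 0] = m[1, 2] = m[2, 1] = 1
        out, bit = ps.partial_conv(v, m, k, bias=0.25)
        hand = (k[0, 0] * v[0, 0] + k[1, 2] * v[1, 2] + k[2, 1] * v[2, 1]) \
            * (9 / 3) + 0.25
        assert bit == 1
        assert out == pytest.approx(hand, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            ps.partial_conv(np.zeros((3, 3)), np.zeros((2, 2)), np.zeros((3, 3)))


class TestBuildModel:
    def test_output_shape_contract(self, rng):
        x = rng.random((2, 32, 32))
        for arch in ("cnn", "partial_cnn"):
            model = ps.build_model(ps.ModelConfig(arch=arch, **SMALL), seed=0)
            out = model.predict(x, np.ones_like(x))
            assert out.shape == x.shape
            assert out.min() >= 0 and out.max() <= 1

    def test_all_valid_mask_forward_equals_weight_shared_cnn(self, rng):
        """Partial-conv network under an all-ones mask is exactly the plain CNN."""
        mp = ps.build_model(ps.ModelConfig(arch="partial_cnn", **SMALL), seed=3)
        mc = ps.build_model(ps.ModelConfig(arch="cnn", **SMALL), seed=4)
        # give the correction head nonzero weights so the test is non-trivial
        for m in (mp, mc):
            m.params["out_w"].data[:] = 0.01
        mc.copy_weights_from(mp)
        x = rng.random((2, 32, 32))
        diff = np.abs(mp.predict(x, np.ones_like(x)) - mc.predict(x)).max()
        assert diff <= 1e-5

    def test_parameter_count_partial_not_larger(self):
        mp = ps.build_model(ps.ModelConfig(arch="partial_cnn", **SMALL))
        mc = ps.build_model(ps.ModelConfig(arch="cnn", **SMALL))
        assert mp.n_parameters <= mc.n_parameters

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigurationError):
            ps.ModelConfig(filters=(4, 8, 16), input_size=(36, 36))

    def test_filter_ladder_must_be_monotone(self):
        with pytest.raises(ConfigurationError):
            ps.ModelConfig(filters=(64, 32), input_size=(32, 32))

    def test_save_load_roundtrip(self, tmp_path, rng):
        m = ps.build_model(ps.ModelConfig(arch="partial_cnn", **SMALL), seed=5)
        path = m.save(tmp_path / "model.npz")
        back = ps.InpaintingModel.load(path)
        x = rng.random((1, 32, 32))
        assert np.array_equal(m.predict(x, np.ones_like(x)),
                              back.predict(x, np.ones_like(x)))


class TestCombinedLoss:
    def test_identical_images_zero(self, rng):
        a = rng.random((32, 32))
        assert ps.combined_loss(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_zero_reduces_to_mse(self):
        lc = ps.LossConfig(alpha=0.0)
        assert ps.combined_loss(np.zeros((16, 16)), np.ones((16, 16)), lc) \
            == pytest.approx(1.0)

    def test_termwise_oracle_at_alpha_096(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        lc = ps.LossConfig(alpha=0.96, ssim_window=11)
        expect = 0.96 * (1 - ps.ssim(a, b, window=11)) + 0.04 * ps.mse(a, b)
        assert ps.combined_loss(a, b, lc) == pytest.approx(expect, abs=1e-12)

    def test_autodiff_graph_matches_numpy_loss(self, rng):
        a, b = rng.random((1, 1, 32, 32)), rng.random((1, 1, 32, 32))
        lc = ps.LossConfig()
        graph_val = float(loss_graph(ad.Tensor(b), a, lc).data)
        numpy_val = ps.combined_loss(a[0, 0], b[0, 0], lc)
        assert graph_val == pytest.approx(numpy_val, abs=1e-9)


class TestInterpolateLinear:
    def test_midpoint(self):
        vals = np.array([[0.2, 0.2], [0.0, 0.0], [0.8, 0.8]])
        h = ps.HeightMap(values=vals, norm_state="unit_normalized")
        mask = MaskRaster(values=np.array([[1, 1], [0, 0], [1, 1]]))
        out = ps.interpolate_linear(h, mask)
        assert np.allclose(out.values[1], 0.5)

    def test_exact_on_row_linear_images(self, rng):
        ramp = np.tile(np.linspace(0, 1, 32)[:, None], (1, 16))
        h = ps.HeightMap(values=ramp, norm_state="unit_normalized")
        lm = ps.random_line_mask(32, 0.3, seed=2)
        partial, raster = ps.acquire_partial(h, lm)
        out = ps.interpolate_linear(partial, raster)
        assert ps.mse(h, out) < 1e-18

    def test_all_keep_identity(self, small_scene):
        mask = MaskRaster(values=np.ones((64, 64)))
        out = ps.interpolate_linear(small_scene, mask)
        assert np.array_equal(out.values, small_scene.values)

    def test_skipped_boundary_rejected(self, small_scene):
        m = np.ones((64, 64))
        m[0] = 0
        with pytest.raises(ParameterError):
            ps.interpolate_linear(small_scene, MaskRaster(values=m))


class TestMedianLineCorrect:
    def test_single_scar_midpoint_of_neighbours(self):
        vals = np.array([[0.0, 2.0], [9.0, 9.0], [1.0, 4.0]])
        h = ps.HeightMap(values=vals)
        lm = ps.LineMask(keep=np.array([1, 0, 1], dtype=bool),
                         fraction=1 / 3, pattern="scar")
        out = ps.median_line_correct(h, lm)
        assert np.allclose(out.values[1], [0.5, 3.0])

    def test_no_flagged_rows_identity(self, small_scene):
        lm = ps.LineMask(keep=np.ones(64, dtype=bool), fraction=0.0,
                         pattern="scar")
        out = ps.median_line_correct(small_scene, lm)
        assert np.array_equal(out.values, small_scene.values)

    def test_two_adjacent_scars_hand_worked_toy(self):
        # 5x3 toy: rows 2 and 3 scarred; nearest clean rows are 1 and 4
        vals = np.arange(15, dtype=float).reshape(5, 3)
        vals[2] += 100
        vals[3] -= 50
        h = ps.HeightMap(values=vals)
        lm = ps.LineMask(keep=np.array([1, 1, 0, 0, 1], dtype=bool),
                         fraction=0.4, pattern="scar")
        out = ps.median_line_correct(h, lm)
        expect = 0.5 * (vals[1] + vals[4])
        assert np.allclose(out.values[2], expect)
        assert np.allclose(out.values[3], expect)

    def test_scar_at_border_without_neighbour_rejected(self):
        h = ps.HeightMap(values=np.zeros((4, 2)))
        lm = ps.LineMask(keep=np.array([0, 1, 1, 1], dtype=bool),
                         fraction=0.25, pattern="scar")
        with pytest.raises(CorrectionError):
            ps.median_line_correct(h, lm)


class TestReconstructCompositing:
    @pytest.fixture(scope="class")
    def untrained(self):
        return ps.build_model(
            ps.ModelConfig(arch="partial_cnn", filters=(4, 8),
                           input_size=(64, 64)), seed=0)

    def test_all_keep_mask_is_identity(self, untrained, small_scene):
        mask = MaskRaster(values=np.ones((64, 64)))
        out = ps.reconstruct(untrained, small_scene, mask)
        assert np.array_equal(out.values, small_scene.values)

    def test_scanned_rows_never_altered(self, untrained):
        for seed in range(10):
            scene = ps.normalize(ps.generate_scene(
                ps.SceneParams(image_size=(64, 64), seed=seed)))
            lm = ps.random_line_mask(64, 0.35, seed=seed)
            partial, raster = ps.acquire_partial(scene, lm)
            out = ps.reconstruct(untrained, partial, raster)
            assert np.array_equal(out.values[lm.keep], scene.values[lm.keep])

    def test_shape_mismatch(self, untrained, small_scene):
        with pytest.raises(DimensionError):
            ps.reconstruct(untrained, small_scene,
                           MaskRaster(values=np.ones((32, 32))))


class TestTraining:
    def test_smoke_run_decreases_loss_and_is_deterministic(self):
        scenes = [ps.normalize(ps.generate_scene(
            ps.SceneParams(image_size=(32, 32), seed=s))) for s in range(24)]
        tc = ps.TrainConfig(folds=2, max_epochs=4, patience=4, seed=3)
        lc = ps.LossConfig()
        cfg = ps.ModelConfig(arch="partial_cnn", filters=(4, 8),
                             input_size=(32, 32))
        m1 = ps.train(ps.build_model(cfg, seed=0), scenes, tc=tc, lc=lc)
        hist = m1.training_history
        assert m1.trained
        first = [h["train_loss"] for h in hist if h["fold"] == 0]
        assert first[-1] <= first[0]  # smoothed downward trend at smoke scale
        m2 = ps.train(ps.build_model(cfg, seed=0), scenes, tc=tc, lc=lc)
        assert m2.training_history == hist  # bit-deterministic per seed

    def test_fold_bookkeeping(self):
        scenes = [ps.normalize(ps.generate_scene(
            ps.SceneParams(image_size=(32, 32), seed=s))) for s in range(8)]
        tc = ps.TrainConfig(folds=2, max_epochs=2, patience=2, seed=1)
        cfg = ps.ModelConfig(arch="cnn", filters=(4, 8), input_size=(32, 32))
        m = ps.train(ps.build_model(cfg, seed=0), scenes, tc=tc)
        folds = {h["fold"] for h in m.training_history}
        assert folds == {0, 1}

    def test_empty_dataset_rejected(self):
        from partialscan.errors import DataError

        cfg = ps.ModelConfig(arch="cnn", filters=(4, 8), input_size=(32, 32))
        with pytest.raises(DataError):
            ps.train(ps.build_model(cfg), [], tc=ps.TrainConfig(folds=2))
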