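"""Segmentation module: block shapes, mask rules, loss identities, training."""

import math
import warnings

import numpy as np
import pytest

from histosynth.nn import Tensor
from histosynth.segmodule import (RDB, RUB, SegModule, SegModuleConfig,
                                  mask_from_probs, recon_loss, seg_loss,
                                  total_loss, train_seg_module)


def _zero_module(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


class TestBlocks:
    def test_rdb_halves_spatial_size(self):
        rng = np.random.default_rng(0)
        block = RDB(3, 64, 0.2, rng)
        out = block(Tensor(rng.standard_normal((1, 3, 256, 256)).astype(np.float32)))
        assert out.shape == (1, 64, 128, 128)

    def test_rdb_rejects_odd_dims(self):
        block = RDB(3, 8, 0.2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="even"):
            block(Tensor(np.zeros((1, 3, 7, 8), np.float32)))

    def test_zero_initialized_rdb_outputs_zero(self):
        block = RDB(3, 8, 0.2, np.random.default_rng(0))
        _zero_module(block)
        out = block(Tensor(np.random.default_rng(1).random((1, 3, 8, 8)).astype(np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_separable_path_has_fewer_parameters_than_plain_conv(self):
        cin, cout, k = 64, 128, 3
        block = RDB(cin, cout, 0.2, np.random.default_rng(0))
        sep_params = (block.sep1.depthwise.weight.size + block.sep1.pointwise.weight.size)
        plain_params = k * k * cin * cout
        assert sep_params == k * k * cin + cin * cout
        assert sep_params < plain_params

    def test_rub_doubles_spatial_size_to_printed_shape(self):
        rng = np.random.default_rng(0)
        block = RUB(512, 256, 0.2, rng)
        out = block(Tensor(rng.standard_normal((1, 512, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 256, 32, 32)

    def test_rub_then_rdb_preserves_spatial_size(self):
        rng = np.random.default_rng(0)
        up = RUB(8, 8, 0.2, rng)
        down = RDB(8, 8, 0.2, rng)
        x = Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32))
        assert down(up(x)).shape == (1, 8, 16, 16)

    def test_upsample_of_constant_is_constant(self):
        from histosynth.nn import autograd as ag
        x = Tensor(np.full((1, 2, 4, 4), 1.5, np.float32))
        np.testing.assert_array_equal(ag.upsample2(x).data, 1.5)


class TestForwardContracts:
    cfg = SegModuleConfig(input_size=32, stem_channels=8)

    @pytest.fixture(scope="class")
    def module(self):
        return SegModule(self.cfg, seed=0)

    def test_probabilities_sum_to_one(self, module, rng):
        probs = module.segment(rng.random((32, 32, 3)))
        assert probs.shape == (32, 32, 4)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert probs.min() >= 0

    def test_segment_is_deterministic(self, module, rng):
        x = rng.random((32, 32, 3))
        np.testing.assert_array_equal(module.segment(x), module.segment(x))

    def test_wrong_input_size_rejected(self, module):
        with pytest.raises(ValueError, match="expected input"):
            module.segment(np.zeros((16, 16, 3)))

    def test_reconstruction_bounded_by_tanh(self, module, rng):
        out = module.reconstruct(rng.random((32, 32)))
        assert out.shape == (32, 32, 3)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_untrained_feature_extraction_warns_but_returns(self, module, rng):
        with pytest.warns(UserWarning, match="untrained"):
            emb = module.extract_features(rng.random((32, 32, 3)))
        assert emb.f_enc.shape == (2, 2, 64)


@pytest.mark.parametrize("size,stem,expected", [
    (256, 64, {"f_enc": (16, 16, 512), "f_dec1": (32, 32, 256), "f_dec2": (64, 64, 128)}),
    (64, 64, {"f_enc": (4, 4, 512), "f_dec1": (8, 8, 256), "f_dec2": (16, 16, 128)}),
])
def test_embedding_shapes_follow_input_scaling(size, stem, expected):
    cfg = SegModuleConfig(input_size=size, stem_channels=stem)
    assert cfg.feature_shapes == expected


class TestMaskFromProbs:
    def test_argmax_class_maps_to_unit_interval(self):
        probs = np.zeros((2, 2, 4))
        probs[..., 3] = 1.0
        np.testing.assert_allclose(mask_from_probs(probs, "hard"), 1.0)
        probs = np.zeros((2, 2, 4))
        probs[..., 0] = 1.0
        np.testing.assert_allclose(mask_from_probs(probs, "hard"), 0.0)

    def test_hard_and_soft_agree_on_one_hot(self):
        probs = np.zeros((1, 1, 4))
        probs[..., 1] = 1.0
        assert mask_from_probs(probs, "hard")[0, 0] == pytest.approx(1 / 3)
        assert mask_from_probs(probs, "soft")[0, 0] == pytest.approx(1 / 3)

    def test_soft_is_expected_value(self):
        probs = np.array([[[0.5, 0.0, 0.0, 0.5]]])
        assert mask_from_probs(probs, "soft")[0, 0] == pytest.approx(0.5)

    def test_single_class_guard(self):
        probs = np.ones((3, 3, 1))
        np.testing.assert_array_equal(mask_from_probs(probs, "hard"), 0.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            mask_from_probs(np.ones((1, 1, 2)) / 2, "median")


class TestLosses:
    def test_perfect_predictions_have_zero_cce(self):
        classes = np.array([[0, 1], [2, 3]])
        probs = np.eye(4)[classes]
        assert seg_loss(probs, classes) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_predictions_give_log_k(self):
        probs = np.full((5, 5, 4), 0.25)
        classes = np.zeros((5, 5), dtype=int)
        assert seg_loss(probs, classes) == pytest.approx(math.log(4), abs=1e-6)

    def test_hand_computed_two_pixel_case(self):
        probs = np.array([[[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]]])
        classes = np.array([[0, 2]])
        expected = (-math.log(0.7) - math.log(0.25)) / 2
        assert seg_loss(probs, classes) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.8715, abs=5e-5)

    def test_zero_probability_clamped_with_warning(self):
        probs = np.zeros((1, 1, 4))
        probs[..., 1] = 1.0
        classes = np.array([[0]])
        with pytest.warns(UserWarning, match="clamp"):
            val = seg_loss(probs, classes)
        assert val == pytest.approx(-math.log(1e-12))

    @pytest.mark.parametrize("offset,expected", [(0.0, 0.0), (0.1, 0.01), (2.0, 4.0)])
    def test_recon_loss_constant_offsets(self, offset, expected):
        x = np.full((4, 4, 3), -1.0)
        assert recon_loss(x + offset, x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("l_seg,l_rec,lam,expected", [
        (1.0, 0.2, 5.0, 2.0), (0.0, 0.0, 7.0, 0.0), (0.5, 0.3, 5.0, 2.0)])
    def test_total_loss_arithmetic(self, l_seg, l_rec, lam, expected):
        assert total_loss(l_seg, l_rec, lam) == pytest.approx(expected)


class TestTraining:
    def _toy(self, n=12):
        from histosynth.synthetic import PatchSpec, generate_patches
        from histosynth.clustering import assign_guide, fit_pixel_clusters
        spec = PatchSpec(height=32, width=32, nucleus_count=3,
                         nucleus_radius_range=(3, 5), halo_width=1, noise_sigma=0.0)
        patches, _ = generate_patches(n, spec, seed=50)
        guide = fit_pixel_clusters(patches, 4, seed=2)
        return patches, [assign_guide(p, guide) for p in patches]

    def test_zero_epochs_returns_initial_weights(self):
        patches, guides = self._toy(4)
        cfg = SegModuleConfig(input_size=32, stem_channels=8)
        module, history = train_seg_module(patches, guides, cfg, epochs=0,
                                           batch_size=4, seed=0)
        assert history == []
        fresh = SegModule(cfg, seed=np.random.default_rng(0).integers(2 ** 31))
        for (na, a), (nb, b) in zip(sorted(module.named_parameters().items()),
                                    sorted(fresh.named_parameters().items())):
            assert na == nb
            np.testing.assert_array_equal(a.data, b.data)

    def test_zero_lambda_makes_total_equal_seg_loss(self):
        patches, guides = self._toy(8)
        cfg = SegModuleConfig(input_size=32, stem_channels=8, lambda_recon=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, history = train_seg_module(patches, guides, cfg, epochs=2,
                                          batch_size=4, seed=1)
        for h in history:
            assert h["l_total"] == pytest.approx(h["l_seg"])

    def test_empty_dataset_rejected(self):
        cfg = SegModuleConfig(input_size=32, stem_channels=8)
        with pytest.raises(ValueError):
            train_seg_module([], [], cfg, epochs=1, batch_size=4, seed=0)

    def test_history_tracks_both_losses(self):
        patches, guides = self._toy(8)
        cfg = SegModuleConfig(input_size=32, stem_channels=8)
        _, history = train_seg_module(patches, guides, cfg, epochs=2,
                                      batch_size=4, seed=3)
        assert [h["epoch"] for h in history] == [0, 1]
        for h in history:
            assert h["l_total"] == pytest.approx(
                h["l_seg"] + cfg.lambda_recon * h["l_recon"])


def test_trained_reconstruction_beats_constant_gray_baseline(desk_dataset,
                                                             desk_trained_seg):
    """R(S(x)) should reconstruct patches better than predicting mid-gray."""
    patches, _ = desk_dataset
    module, _ = desk_trained_seg
    mses, baselines = [], []
    for p in patches[:10]:
        probs = module.segment(p)
        recon = module.reconstruct(mask_from_probs(probs, "hard"))
        target = p * 2.0 - 1.0
        mses.append(recon_loss(recon, target))
        baselines.append(recon_loss(np.zeros_like(target), target))
    assert np.mean(mses) < np.mean(baselines)


def test_trained_features_are_deterministic(desk_dataset, desk_trained_seg):
    patches, _ = desk_dataset
    module, _ = desk_trained_seg
    e1 = module.extract_features(patches[0])
    e2 = module.extract_features(patches[0])
    np.testing.assert_array_equal(e1.f_enc, e2.f_enc)
    np.testing.assert_array_equal(e1.f_dec2, e2.f_dec2)
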