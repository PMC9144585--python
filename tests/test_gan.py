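"""Progressive GAN: fade-in, gradient penalty analytics, stage growth, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histosynth.gan import (Discriminator, GanConfig, Generator, StageState,
                            fade_blend, gan_losses, gradient_penalty, sample,
                            stage_resolutions, train_gan)
from histosynth.nn import Tensor
from histosynth.nn import autograd as ag


def test_stage_resolutions_are_powers_of_two():
    assert stage_resolutions(32) == [4, 8, 16, 32]
    assert stage_resolutions(256) == [4, 8, 16, 32, 64, 128, 256]
    with pytest.raises(ValueError):
        stage_resolutions(48)


class TestFadeBlend:
    def test_endpoints(self):
        a, b = np.zeros((2, 2)), np.ones((2, 2))
        np.testing.assert_array_equal(fade_blend(a, b, 0.0), a)
        np.testing.assert_array_equal(fade_blend(a, b, 1.0), b)

    def test_midpoint_is_elementwise_mean(self):
        a, b = np.full((3,), 0.2), np.full((3,), 0.8)
        np.testing.assert_allclose(fade_blend(a, b, 0.5), 0.5)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fade_blend(np.zeros(2), np.zeros(2), 1.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fade_blend(np.zeros(2), np.zeros(3), 0.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.0, 1.0))
    def test_blend_of_bounded_images_stays_bounded(self, alpha):
        rng = np.random.default_rng(4)
        a = rng.uniform(-1, 1, (4, 4, 3))
        b = rng.uniform(-1, 1, (4, 4, 3))
        out = fade_blend(a, b, alpha)
        assert out.min() >= -1.0 and out.max() <= 1.0


class TestGradientPenalty:
    """Analytic penalties for critics with known input gradients (lambda=10)."""

    x_real = np.random.default_rng(0).random((3, 1, 2, 2)).astype(np.float32)
    x_fake = np.random.default_rng(1).random((3, 1, 2, 2)).astype(np.float32)

    def test_constant_critic_penalty_is_lambda(self):
        critic = lambda t: ag.mul(ag.tsum(ag.reshape(t, (3, 4)), axis=1,
                                          keepdims=True), Tensor(np.float32(0.0)))
        gp = gradient_penalty(critic, self.x_real, self.x_fake, 10.0,
                              np.random.default_rng(2))
        assert gp.item() == pytest.approx(10.0, abs=1e-5)

    def test_sum_critic_of_four_elements(self):
        # gradient is all-ones over 4 entries -> norm 2 -> 10*(2-1)^2 = 10
        critic = lambda t: ag.tsum(ag.reshape(t, (3, 4)), axis=1, keepdims=True)
        gp = gradient_penalty(critic, self.x_real, self.x_fake, 10.0,
                              np.random.default_rng(2))
        assert gp.item() == pytest.approx(10.0, abs=1e-5)

    def test_mean_critic_of_four_elements(self):
        # gradient 1/4 each -> norm 0.5 -> 10*(0.5-1)^2 = 2.5
        critic = lambda t: ag.tmean(ag.reshape(t, (3, 4)), axis=1, keepdims=True)
        gp = gradient_penalty(critic, self.x_real, self.x_fake, 10.0,
                              np.random.default_rng(2))
        assert gp.item() == pytest.approx(2.5, abs=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gradient_penalty(lambda t: t, self.x_real, self.x_fake[:2], 10.0,
                             np.random.default_rng(0))


class TestGanLosses:
    def test_balanced_case(self):
        c, g = gan_losses(np.array([5.0]), np.array([2.0]), 3.0)
        assert c == pytest.approx(0.0)
        assert g == pytest.approx(-2.0)

    def test_identical_scores_cancel(self):
        d = np.array([1.0, -2.0, 0.5])
        c, _ = gan_losses(d, d, 0.0)
        assert c == pytest.approx(0.0)

    def test_antisymmetric_under_swap_without_penalty(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        c1, _ = gan_losses(a, b, 0.0)
        c2, _ = gan_losses(b, a, 0.0)
        assert c1 == pytest.approx(-c2)


FEATURES_32 = {"f_enc": 64, "f_dec1": 32, "f_dec2": 16}


def _zero_features(channels, sizes={"f_enc": 2, "f_dec1": 4, "f_dec2": 8}):
    return {k: np.zeros((sizes[k], sizes[k], c)) for k, c in channels.items()}


class TestGenerator:
    cfg = GanConfig(final_resolution=32, generator_channels=(32, 32, 16, 16))

    @pytest.fixture(scope="class")
    def gen(self):
        return Generator(self.cfg, FEATURES_32, seed=0)

    def test_stage0_output_is_4x4_rgb_without_features(self, gen, rng):
        out = gen.generate(rng.standard_normal((2, 512)), None, StageState(0, 4))
        assert out.shape == (2, 4, 4, 3)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_full_stack_output_bounded(self, gen, rng):
        z = rng.standard_normal((1, 512))
        out = gen.generate(z, _zero_features(FEATURES_32), StageState(3, 32))
        assert out.shape == (1, 32, 32, 3)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_concat_scale_conv_inputs_are_base_plus_feature_channels(self, gen):
        assert gen.conv_input_channels[16] == 32 + 64     # base + f_enc
        assert gen.conv_input_channels[32] == 16 + 32     # base + f_dec1
        assert gen.conv_input_channels[8] == 32           # no conditioning

    def test_feature_channel_mismatch_reported(self, gen, rng):
        bad = _zero_features({**FEATURES_32, "f_enc": 99})
        with pytest.raises(ValueError, match="expected 64"):
            gen.generate(rng.standard_normal((1, 512)), bad, StageState(2, 16))

    def test_repeat_generation_is_identical(self, gen, rng):
        z = rng.standard_normal((2, 512))
        f = _zero_features(FEATURES_32)
        np.testing.assert_array_equal(gen.generate(z, f, StageState(3, 32)),
                                      gen.generate(z, f, StageState(3, 32)))

    def test_different_latents_give_different_images(self, gen, rng):
        f = _zero_features(FEATURES_32)
        a = gen.generate(rng.standard_normal((1, 512)), f, StageState(3, 32))
        b = gen.generate(rng.standard_normal((1, 512)), f, StageState(3, 32))
        assert np.sqrt(np.sum((a - b) ** 2)) > 0

    def test_alpha0_equals_upsampled_previous_stage(self, gen, rng):
        z = rng.standard_normal((2, 512))
        f = _zero_features(FEATURES_32)
        prev = gen.generate(z, f, StageState(2, 16, alpha=1.0))
        grown = gen.generate(z, f, StageState(3, 32, alpha=0.0))
        up = np.repeat(np.repeat(prev, 2, axis=1), 2, axis=2)
        np.testing.assert_allclose(grown, up, atol=1e-6)

    def test_default_256_config_concat_bookkeeping(self):
        cfg = GanConfig()            # 256, channels 512..32
        gen = Generator(cfg, {"f_enc": 512, "f_dec1": 256, "f_dec2": 128}, seed=1)
        assert gen.conv_input_channels[16] == 512 + 512
        assert gen.conv_input_channels[32] == 512 + 256
        assert gen.conv_input_channels[64] == 256 + 128


class TestDiscriminator:
    cfg = GanConfig(final_resolution=32, generator_channels=(32, 32, 16, 16))

    @pytest.fixture(scope="class")
    def disc(self):
        return Discriminator(self.cfg, seed=0)

    @pytest.mark.parametrize("stage,res", [(0, 4), (1, 8), (2, 16), (3, 32)])
    def test_scalar_output_at_every_stage(self, disc, rng, stage, res):
        scores = disc.score(rng.standard_normal((2, 3, res, res)), StageState(stage, res))
        assert scores.shape == (2,)

    def test_deterministic_scoring(self, disc, rng):
        x = rng.standard_normal((1, 3, 32, 32))
        s = StageState(3, 32)
        assert disc.score(x, s) == disc.score(x, s)


class TestTraining:
    def _setup(self, n=16):
        import warnings

        from histosynth.clustering import assign_guide, fit_pixel_clusters
        from histosynth.segmodule import SegModuleConfig, train_seg_module
        from histosynth.synthetic import PatchSpec, generate_patches
        spec = PatchSpec(height=32, width=32, nucleus_count=3,
                         nucleus_radius_range=(3, 5), halo_width=1)
        patches, _ = generate_patches(n, spec, seed=60)
        guide = fit_pixel_clusters(patches, 4, seed=2)
        guides = [assign_guide(p, guide) for p in patches]
        cfg = SegModuleConfig(input_size=32, stem_channels=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seg, _ = train_seg_module(patches, guides, cfg, epochs=1,
                                      batch_size=8, seed=3)
        return patches, seg

    def test_zero_schedule_returns_initial_networks(self):
        patches, seg = self._setup(8)
        cfg = GanConfig(final_resolution=16, generator_channels=(16, 16, 8))
        gen, disc, logs = train_gan(patches, seg, cfg, [0, 0, 0], seed=1)
        assert all(log == [] for log in logs.values())

    def test_untrained_seg_module_aborts(self):
        from histosynth.segmodule import SegModule, SegModuleConfig
        seg = SegModule(SegModuleConfig(input_size=32, stem_channels=8), seed=0)
        cfg = GanConfig(final_resolution=16, generator_channels=(16, 16, 8))
        with pytest.raises(RuntimeError, match="pre-trained"):
            train_gan([np.zeros((32, 32, 3))], seg, cfg, [1, 1, 1], seed=0)

    def test_short_run_logs_and_loss_csvs(self, tmp_path):
        patches, seg = self._setup(12)
        cfg = GanConfig(final_resolution=16, generator_channels=(16, 16, 8))
        gen, disc, logs = train_gan(patches, seg, cfg, [4, 4, 4], seed=5,
                                    out_dir=tmp_path, batch_size=2)
        assert sorted(logs) == [4, 8, 16]
        for res, log in logs.items():
            assert len(log) == 4
            assert all(np.isfinite(e["critic_loss"]) and
                       np.isfinite(e["generator_loss"]) for e in log)
            assert (tmp_path / f"losses_res{res}.csv").exists()

    def test_sampling_contract(self):
        patches, seg = self._setup(8)
        cfg = GanConfig(final_resolution=16, generator_channels=(16, 16, 8))
        gen, _, _ = train_gan(patches, seg, cfg, [2, 2, 2], seed=7)
        imgs, prov = sample(gen, seg, patches[:3], n=4, seed=11)
        assert imgs.shape == (4, 16, 16, 3)
        assert imgs.min() >= 0.0 and imgs.max() <= 1.0
        assert len(prov) == 4 and all("z_seed" in p for p in prov)
        imgs2, _ = sample(gen, seg, patches[:3], n=4, seed=11)
        np.testing.assert_array_equal(imgs, imgs2)
        empty, _ = sample(gen, seg, patches[:3], n=0, seed=1)
        assert empty.shape[0] == 0
        with pytest.raises(ValueError, match="reference"):
            sample(gen, seg, [], n=2, seed=1)


def test_bad_schedule_length_rejected():
    cfg = GanConfig(final_resolution=16, generator_channels=(16, 16, 8))
    with pytest.raises(ValueError):
        GanConfig(final_resolution=16, generator_channels=(16, 16))
    from histosynth.segmodule import SegModule, SegModuleConfig
    seg = SegModule(SegModuleConfig(input_size=32, stem_channels=8), seed=0)
    seg.trained = True
    with pytest.raises(ValueError, match="schedule"):
        train_gan([np.zeros((32, 32, 3))], seg, cfg, [1, 1], seed=0)
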