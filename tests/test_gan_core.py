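import numpy as np
import pytest

from bnloopgan import nn
from bnloopgan.gan_core import (LayerSpec, Network, TrainingConfig,
                                build_classifier, build_discriminator,
                                build_generator, classifier_logit,
                                classifier_loss, condition_inputs,
                                critic_scores, discriminator_loss,
                                generator_loss, gradient_penalty,
                                output_shape, pretrain_gan)
from bnloopgan.nn import autodiff as ad
from bnloopgan.nn.autodiff import Tensor

# every "size of feature map" cell of the published layer table
GENERATOR_TRACE = [(4, 4, 512), (8, 8, 256), (16, 16, 128), (32, 32, 64),
                   (41, 41, 32), (82, 82, 16)]
CRITIC_TRACE = [(82, 82, 16), (41, 41, 64), (32, 32, 128), (16, 16, 256),
                (8, 8, 512)]


class TestOutputShape:
    def test_transposed_conv_row_from_32_to_41(self):
        layer = LayerSpec("transposed_conv", 12, 1, 1, 32)
        assert output_shape(layer, (32, 32, 64)) == (41, 41, 32)

    def test_conv_row_from_41_to_32(self):
        layer = LayerSpec("conv", 10, 1, 0, 128)
        assert output_shape(layer, (41, 41, 64)) == (32, 32, 128)

    def test_unit_kernel_preserves_spatial_size(self):
        layer = LayerSpec("conv", 1, 1, 0, 7)
        assert output_shape(layer, (13, 13, 3)) == (13, 13, 7)

    def test_nonpositive_size_names_the_layer(self):
        layer = LayerSpec("conv", 9, 1, 0, 4, name="Conv 99")
        with pytest.raises(ValueError, match="Conv 99"):
            output_shape(layer, (5, 5, 1))


class TestArchitectures:
    @pytest.mark.parametrize("n", [1, 2])
    def test_generator_trace_reproduces_published_cells(self, n):
        trace = build_generator(n).shape_trace()
        assert trace[0] == (1, 1, 100 * n)
        assert trace[1:-1] == GENERATOR_TRACE
        assert trace[-1] == (164, 164, n)

    @pytest.mark.parametrize("n", [1, 2])
    def test_discriminator_trace_ends_in_5x5_patch_map(self, n):
        trace = build_discriminator(n).shape_trace()
        assert trace[1:-1] == CRITIC_TRACE
        assert trace[-1] == (5, 5, n)

    @pytest.mark.parametrize("n", [1, 2])
    def test_classifier_trace_ends_in_2x2_map(self, n):
        trace = build_classifier(n).shape_trace()
        assert trace[1:-1] == CRITIC_TRACE
        assert trace[-1] == (2, 2, 1)

    def test_invalid_modality_count_rejected(self):
        with pytest.raises(ValueError):
            build_generator(0)

    def test_full_size_forward_passes_match_traces(self, rng):
        gen = Network(build_generator(1), rng)
        z = Tensor(rng.normal(size=(1, 100)))
        out = gen(z)
        assert out.shape == (1, 1, 164, 164)
        assert out.data.min() >= 0 and out.data.max() <= 1
        critic = Network(build_discriminator(1), rng)
        assert critic(out).shape == (1, 1, 5, 5)
        clf = Network(build_classifier(1), rng)
        assert clf(out).shape == (1, 1, 2, 2)

    def test_reduced_geometry_forward_shapes(self, rng):
        gen = Network(build_generator(2, image_size=40, width=0.25), rng)
        out = gen(Tensor(rng.normal(size=(3, 200))))
        assert out.shape == (3, 2, 40, 40)
        critic = Network(build_discriminator(2, image_size=40, width=0.25), rng)
        assert critic(out).shape == (3, 2, 5, 5)
        clf = Network(build_classifier(2, image_size=40, width=0.25), rng)
        assert clf(out).shape == (3, 1, 2, 2)

    def test_unsupported_reduced_size_rejected(self):
        with pytest.raises(ValueError, match="5\\*2"):
            build_generator(1, image_size=37)


class TestConditioning:
    def test_latent_conditioning_appends_one_hot(self, rng):
        z = rng.normal(size=(4, 100))
        zc = condition_inputs(z, [0, 1, 1, 0])
        assert zc.shape == (4, 102)
        np.testing.assert_array_equal(zc[:, 100:],
                                      [[1, 0], [0, 1], [0, 1], [1, 0]])

    def test_image_conditioning_adds_constant_channel(self, rng):
        x = rng.normal(size=(2, 3, 8, 8))
        xc = condition_inputs(x, [1, 0])
        assert xc.shape == (2, 4, 8, 8)
        assert (xc[0, 3] == 1).all() and (xc[1, 3] == 0).all()

    def test_conditional_specs_extend_channel_counts(self):
        assert build_generator(2, conditional=True).input_shape == (1, 1, 202)
        assert build_discriminator(2, conditional=True).input_shape[2] == 3
        # conditioning off reduces exactly to the tabulated counts
        assert build_generator(2).input_shape == (1, 1, 200)
        assert build_discriminator(2).input_shape[2] == 2

    def test_unknown_label_rejected(self, rng):
        with pytest.raises(ValueError, match="label"):
            condition_inputs(rng.normal(size=(1, 10)), [3])


class _UnitGradientCritic(nn.Module):
    """D(x) = sum(x) / sqrt(d): input-gradient norm exactly 1 everywhere."""

    def __init__(self, d):
        super().__init__()
        self.d = d

    def forward(self, x):
        flat = ad.reshape(x, (x.shape[0], self.d))
        s = ad.sum_(flat, axis=1) * Tensor(1.0 / np.sqrt(self.d))
        return ad.reshape(s, (x.shape[0], 1, 1, 1))


class _ConstantCritic(nn.Module):
    def forward(self, x):
        return Tensor(np.full((x.shape[0], 1, 1, 1), 3.25))


class TestGradientPenalty:
    def test_unit_gradient_critic_has_zero_penalty(self, rng):
        d = 2 * 6 * 6
        real = rng.uniform(size=(4, 2, 6, 6))
        fake = rng.uniform(size=(4, 2, 6, 6))
        gp = gradient_penalty(real, fake, _UnitGradientCritic(d), rng)
        assert gp.item() == pytest.approx(0.0, abs=1e-10)

    def test_constant_critic_has_unit_penalty(self, rng):
        real = rng.uniform(size=(3, 1, 5, 5))
        fake = rng.uniform(size=(3, 1, 5, 5))
        gp = gradient_penalty(real, fake, _ConstantCritic(), rng)
        assert gp.item() == pytest.approx(1.0, rel=1e-5)

    def test_penalty_matches_finite_difference_oracle(self, rng):
        critic = nn.Sequential(nn.Conv2d(1, 2, 3, 1, 1, rng=rng),
                               nn.LeakyReLU(0.2),
                               nn.Conv2d(2, 1, 4, 2, 1, rng=rng))
        real = rng.uniform(size=(2, 1, 8, 8))
        fake = rng.uniform(size=(2, 1, 8, 8))
        gp = gradient_penalty(real, fake, critic,
                              np.random.default_rng(5)).item()

        eps_rng = np.random.default_rng(5)
        eps = eps_rng.uniform(size=(2, 1, 1, 1))
        xhat = eps * real + (1 - eps) * fake

        def scalar(x):
            return float(critic(Tensor(x)).data.reshape(2, -1).mean(axis=1)[i])

        h = 1e-6
        penalties = []
        for i in range(2):
            g = np.zeros(xhat[i].size)
            for j in range(xhat[i].size):
                xp = xhat.copy()
                xp[i].ravel()[j] += h
                xm = xhat.copy()
                xm[i].ravel()[j] -= h
                g[j] = (scalar(xp) - scalar(xm)) / (2 * h)
            penalties.append((np.linalg.norm(g) - 1) ** 2)
        assert gp == pytest.approx(np.mean(penalties), abs=1e-4)

    def test_mismatched_batches_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            gradient_penalty(np.zeros((2, 1, 4, 4)), np.zeros((3, 1, 4, 4)),
                             _ConstantCritic(), rng)


class TestLosses:
    def test_equal_scores_and_no_penalty_cancel(self):
        d = Tensor(np.array([0.7, -0.2]))
        assert discriminator_loss(d, d, 0.0, 10.0).item() == pytest.approx(0.0)

    def test_critic_loss_arithmetic(self):
        d_real = Tensor(np.array([1.0, 1.0]))
        d_fake = Tensor(np.array([2.0, 2.0]))
        loss = discriminator_loss(d_real, d_fake, 0.5, 10.0)
        assert loss.item() == pytest.approx(2 - 1 + 5)

    def test_negative_penalty_coefficient_rejected(self):
        with pytest.raises(ValueError):
            discriminator_loss(Tensor([0.0]), Tensor([0.0]), 0.0, -1.0)

    def test_zero_lambda_reduces_to_negated_score_gap(self, rng):
        d_real = Tensor(rng.normal(size=(8,)))
        d_fake = Tensor(rng.normal(size=(8,)))
        loss = discriminator_loss(d_real, d_fake, 0.0, 0.0)
        gap = d_real.data.mean() - d_fake.data.mean()
        assert loss.item() == pytest.approx(-gap)

    def test_generator_loss_is_negated_mean(self):
        assert generator_loss(Tensor(np.array([3.0, 3.0]))).item() == -3.0

    def test_generator_loss_monotone_in_scores(self, rng):
        d = rng.normal(size=(5,))
        assert generator_loss(Tensor(d + 1)).item() < generator_loss(Tensor(d)).item()

    def test_generator_and_fake_term_of_critic_loss_cancel(self, rng):
        d_fake = Tensor(rng.normal(size=(6,)))
        fake_term = ad.mean(d_fake).item()
        assert generator_loss(d_fake).item() + fake_term == pytest.approx(0.0)

    def test_empty_score_batch_rejected(self):
        with pytest.raises(ValueError):
            generator_loss(Tensor(np.empty(0)))

    def test_critic_summary_is_patch_map_mean(self, rng):
        critic = _ConstantCritic()
        s = critic_scores(critic, Tensor(rng.normal(size=(2, 1, 4, 4))))
        np.testing.assert_allclose(s.data, [3.25, 3.25])


class TestClassifierReadout:
    def test_zero_map_gives_probability_half(self):
        logits = classifier_logit(Tensor(np.zeros((1, 1, 2, 2))))
        assert logits.data[0] == 0.0
        assert 1 / (1 + np.exp(-logits.data[0])) == pytest.approx(0.5)

    def test_unit_map_loss_closed_form(self):
        logits = classifier_logit(Tensor(np.ones((1, 1, 2, 2))))
        loss = classifier_loss(logits, [1])
        assert loss.item() == pytest.approx(np.log(1 + np.exp(-1.0)))

    def test_three_sample_cross_entropy_oracle(self):
        z = np.array([0.5, -1.2, 2.0])
        y = np.array([1, 0, 1])
        loss = classifier_loss(Tensor(z), y)
        p = 1 / (1 + np.exp(-z))
        expect = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert loss.item() == pytest.approx(expect, abs=1e-12)

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            classifier_loss(Tensor(np.zeros(2)), [0, 2])


class TestPretrain:
    def test_smoke_run_logs_losses_and_bounded_output(self, desk_gan,
                                                      desk_dataset):
        assert len(desk_gan.log) > 0
        for entry in desk_gan.log:
            assert np.isfinite(entry["L_D"]) and np.isfinite(entry["gp"])
        gen_steps = [e for e in desk_gan.log if np.isfinite(e["L_G"])]
        assert gen_steps, "no generator updates were logged"
        fakes = desk_gan.sample([0, 1, 0, 1], np.random.default_rng(3))
        assert fakes.shape == (4, 2, 40, 40)
        assert fakes.min() >= 0.0 and fakes.max() <= 1.0

    def test_training_is_bit_reproducible(self, desk_dataset):
        cfg = TrainingConfig(n_modalities=2, image_size=40, width=0.25,
                             epochs=1, batch_size=16, n_critic=5, seed=9)
        a = pretrain_gan(desk_dataset[:16], cfg)
        b = pretrain_gan(desk_dataset[:16], cfg)
        assert a.log == b.log
        za = a.sample([0, 1], np.random.default_rng(0))
        zb = b.sample([0, 1], np.random.default_rng(0))
        np.testing.assert_array_equal(za, zb)

    def test_shape_mismatch_with_config_rejected(self, desk_dataset):
        cfg = TrainingConfig(n_modalities=1, image_size=40, width=0.25)
        with pytest.raises(ValueError, match="does not match"):
            pretrain_gan(desk_dataset, cfg)
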