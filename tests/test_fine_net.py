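import numpy as np
import pytest

from cascadeseg import (ADenseConfig, build_adensenet, build_multires_inputs,
                        fine_forward, fuse_coarse)
from cascadeseg.fine_net import (CPU_TEST_ADENSE, ADenseBlock,
                                 ChannelAttention, _Branch)
from cascadeseg.nn import Tensor, count_convs


def _uniform_prior(h, w):
    return np.full((3, h, w), 1.0 / 3.0)


class TestFusion:
    def test_uniform_prior_on_constant_image(self):
        image = np.full((8, 8), 42.0)
        fused = fuse_coarse(_uniform_prior(8, 8), image)
        # constant image min-max normalises to 0; foreground prior sums to 2/3
        np.testing.assert_allclose(fused, 2.0 / 3.0, atol=1e-6)

    def test_zero_foreground_prior_is_identity_on_normalized_image(self, rng):
        image = rng.random((8, 8))
        prior = np.zeros((3, 8, 8))
        prior[0] = 1.0
        norm = (image - image.min()) / (image.max() - image.min())
        np.testing.assert_allclose(fuse_coarse(prior, image), norm, atol=1e-6)

    def test_localized_prior_adds_its_indicator(self, rng):
        image = rng.random((8, 8))
        prior = np.zeros((3, 8, 8))
        prior[0] = 1.0
        indicator = np.zeros((8, 8))
        indicator[2:4, 3:8] = 1.0  # 10 pixels
        prior[1] = indicator
        prior[0] -= indicator
        base = fuse_coarse(np.concatenate([np.ones((1, 8, 8)),
                                           np.zeros((2, 8, 8))]), image)
        fused = fuse_coarse(prior, image)
        np.testing.assert_allclose(fused - base, indicator, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_coarse(_uniform_prior(8, 8), np.zeros((6, 6)))


class TestMultiresPyramid:
    def test_native_ct_resolution_branches(self):
        sides = [b.shape for b in
                 build_multires_inputs(np.zeros((512, 512), dtype=np.float32))]
        assert sides == [(512, 512), (256, 256), (128, 128)]

    def test_small_input_branches(self):
        sides = [b.shape for b in
                 build_multires_inputs(np.zeros((128, 128), dtype=np.float32))]
        assert sides == [(128, 128), (64, 64), (32, 32)]

    def test_constant_input_stays_constant(self):
        branches = build_multires_inputs(np.full((64, 64), 1.7, dtype=np.float32))
        for b in branches:
            np.testing.assert_allclose(b, 1.7, atol=1e-6)

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_multires_inputs(np.zeros((66, 66), dtype=np.float32))


class TestADenseBlock:
    def test_dense_channel_arithmetic(self, rng):
        cfg = ADenseConfig(width=8, growth_rate=4, dilation_rates=(1, 2, 3))
        block = ADenseBlock(8, cfg, rng)
        assert block.layer_input_channels() == [8, 12, 16]
        assert block.project.in_ch == 20  # input + 3 * growth
        assert block.project.out_ch == 8
        assert count_convs(block) == cfg.n_layers + 1

    def test_single_layer_degenerates_to_conv_plus_projection(self, rng):
        cfg = ADenseConfig(width=8, growth_rate=4, dilation_rates=(1,))
        block = ADenseBlock(8, cfg, rng)
        assert count_convs(block) == 2
        out = block(Tensor(rng.standard_normal((1, 8, 12, 12))))
        assert out.shape == (1, 8, 12, 12)

    @pytest.mark.parametrize("rates", [(1,), (2, 4), (1, 3, 6, 12)])
    def test_spatial_dims_preserved(self, rng, rates):
        cfg = ADenseConfig(width=8, growth_rate=4, dilation_rates=rates)
        block = ADenseBlock(8, cfg, rng)
        out = block(Tensor(rng.standard_normal((2, 8, 16, 16))))
        assert out.shape == (2, 8, 16, 16)

    def test_excessive_dilation_rejected(self):
        with pytest.raises(ValueError, match="sparsely"):
            ADenseConfig(dilation_rates=(1, 3, 24))

    def test_receptive_field_grows_with_dilation_rates(self, rng):
        """The centre output sees exactly radius sum(rates) of the input."""
        rates = (1, 3, 6, 12)
        radius = sum(rates)  # each dilated 3x3 layer adds its rate
        cfg = ADenseConfig(width=4, growth_rate=4, dilation_rates=rates)
        block = ADenseBlock(4, cfg, np.random.default_rng(0))
        side = 2 * radius + 5
        centre = side // 2
        x = rng.standard_normal((1, 4, side, side)).astype(np.float32)
        yy, xx = np.mgrid[0:side, 0:side]
        cheb = np.maximum(np.abs(yy - centre), np.abs(xx - centre))

        def centre_out(arr):
            return block(Tensor(arr)).data[0, :, centre, centre]

        full = centre_out(x)
        inside_only = x * (cheb <= radius)[None, None]
        np.testing.assert_allclose(centre_out(inside_only), full, atol=1e-5)
        for r in (2, 10):
            clipped = x * (cheb <= r)[None, None]
            assert not np.allclose(centre_out(clipped), full, atol=1e-5)


class TestChannelAttention:
    CFG = ADenseConfig(width=8, growth_rate=4, dilation_rates=(1, 2))

    def test_weights_strictly_inside_unit_interval(self, rng):
        att = ChannelAttention(8, self.CFG, rng)
        x = Tensor(rng.standard_normal((2, 8, 8, 8)))
        for w in att.branch_weights(x):
            assert np.all(w.data > 0.0) and np.all(w.data < 1.0)

    def test_calibration_scales_channels(self, rng):
        """A constant feature channel is scaled to weight * value exactly."""
        cfg = ADenseConfig(width=4, growth_rate=4, dilation_rates=(1,),
                           branch_kernels=(1, 1, 1))
        att = ChannelAttention(4, cfg, rng)
        x = Tensor(np.tile(np.arange(1.0, 5.0, dtype=np.float32)
                           .reshape(1, 4, 1, 1), (1, 1, 6, 6)))
        out = att(x)
        # each branch conv of kernel 1 keeps channels constant, so the output
        # must be a sum of weight-scaled constant channels: spatially flat
        assert out.shape == (1, 4, 6, 6)
        np.testing.assert_allclose(
            out.data, np.broadcast_to(out.data[:, :, :1, :1], out.shape),
            atol=1e-5)
        # and reproducible from the published weights and branch features
        expect = np.zeros((1, 4), dtype=np.float64)
        for conv, w in zip(att.branches, att.branch_weights(x)):
            f = conv(x).data[:, :, 0, 0]
            expect += f * w.data
        np.testing.assert_allclose(out.data[:, :, 0, 0], expect, atol=1e-5)

    def test_attention_is_scale_aware(self, rng):
        att = ChannelAttention(8, self.CFG, rng)
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        w1 = att.branch_weights(Tensor(x))[0].data
        x2 = x.copy()
        x2[:, 3] *= 10.0
        w2 = att.branch_weights(Tensor(x2))[0].data
        assert not np.allclose(w1[0, 3], w2[0, 3])
        assert np.all((w2 > 0) & (w2 < 1))

    def test_channel_count_below_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="K"):
            ChannelAttention(2, self.CFG, rng)
        with pytest.raises(ValueError):
            ADenseConfig(width=2, attention_kernel=3)


class TestFineForward:
    def test_three_branch_simplex_output(self, rng):
        net = build_adensenet(CPU_TEST_ADENSE, 0)
        branches = build_multires_inputs(
            rng.random((128, 128), dtype=np.float32))
        probs = fine_forward(net, branches)
        assert probs.shape == (3, 128, 128)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_deterministic_inference(self, rng):
        net = build_adensenet(CPU_TEST_ADENSE, 3)
        branches = build_multires_inputs(rng.random((32, 32), dtype=np.float32))
        np.testing.assert_array_equal(fine_forward(net, branches),
                                      fine_forward(net, branches))

    def test_branch_count_mismatch_rejected(self, rng):
        net = build_adensenet(CPU_TEST_ADENSE, 0)
        branches = build_multires_inputs(rng.random((32, 32), dtype=np.float32))
        with pytest.raises(ValueError, match="branch"):
            fine_forward(net, branches[:2])

    def test_attention_toggle_changes_parameter_count(self):
        from dataclasses import replace
        with_att = build_adensenet(CPU_TEST_ADENSE, 0)
        without = build_adensenet(replace(CPU_TEST_ADENSE, use_attention=False), 0)
        assert with_att.n_parameters() > without.n_parameters()

    def test_gradient_reaches_every_parameter(self, rng):
        from cascadeseg.nn import softmax_cross_entropy
        cfg = ADenseConfig(width=4, growth_rate=4, dilation_rates=(1, 2),
                           resolutions=(1, 2))
        net = build_adensenet(cfg, 0)
        branches = [Tensor(rng.random((2, 1, 16, 16), dtype=np.float32)),
                    Tensor(rng.random((2, 1, 8, 8), dtype=np.float32))]
        labels = rng.integers(0, 3, size=(2, 16, 16))
        loss = softmax_cross_entropy(net(branches), labels)
        loss.backward()
        dead = [n for n, p in net.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []
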