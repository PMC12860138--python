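import numpy as np
import pytest

from histoseg._autodiff import Tensor
from histoseg.network import (
    EncoderConfig,
    InvertedResidual,
    build_model,
    classify,
    count_parameters,
    depthwise_conv,
    grad_cam,
    load_model,
    pointwise_conv,
    save_model,
    segment,
)


def depthwise_reference(feature, kernels, stride, padding):
    """Scalar triple-loop evaluation of the per-channel convolution."""
    h, w, c = feature.shape
    k = kernels.shape[0]
    fp = np.pad(feature, ((padding, padding), (padding, padding), (0, 0)))
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    out = np.zeros((ho, wo, c))
    for ch in range(c):
        for r in range(ho):
            for cc in range(wo):
                for i in range(k):
                    for j in range(k):
                        out[r, cc, ch] += (
                            kernels[i, j, ch] * fp[r * stride + i, cc * stride + j, ch]
                        )
    return out


class TestFunctionalOps:
    def test_identity_kernel_preserves_interior(self, rng):
        feature = rng.normal(0, 1, (6, 6, 2))
        kernels = np.zeros((3, 3, 2))
        kernels[1, 1, :] = 1.0
        out = depthwise_conv(feature, kernels, stride=1, padding=1)
        assert np.allclose(out[1:-1, 1:-1], feature[1:-1, 1:-1])

    def test_constant_channel_times_kernel_sum(self, rng):
        kernels = rng.normal(0, 1, (3, 3, 1))
        feature = np.full((5, 5, 1), 4.0)
        out = depthwise_conv(feature, kernels, stride=1, padding=0)
        assert np.allclose(out, 4.0 * kernels.sum())

    @pytest.mark.parametrize("stride,padding", [(1, 0), (1, 1), (2, 1)])
    def test_depthwise_matches_triple_loop(self, rng, stride, padding):
        feature = rng.normal(0, 1, (5, 5, 2))
        kernels = rng.normal(0, 1, (3, 3, 2))
        ours = depthwise_conv(feature, kernels, stride, padding)
        ref = depthwise_reference(feature, kernels, stride, padding)
        assert np.abs(ours - ref).max() < 1e-6

    def test_kernel_channel_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            depthwise_conv(rng.normal(0, 1, (4, 4, 3)), np.zeros((3, 3, 2)))

    def test_pointwise_identity(self, rng):
        feature = rng.normal(0, 1, (4, 4, 3))
        assert np.allclose(pointwise_conv(feature, np.eye(3)), feature)

    def test_pointwise_all_ones(self):
        feature = np.broadcast_to([1.0, 2.0, 3.0], (4, 4, 3)).copy()
        out = pointwise_conv(feature, np.ones((1, 3)))
        assert np.allclose(out, 6.0)

    def test_pointwise_matches_matmul(self, rng):
        feature = rng.normal(0, 1, (5, 6, 4))
        weights = rng.normal(0, 1, (7, 4))
        ref = np.einsum("hwc,kc->hwk", feature, weights)
        assert np.abs(pointwise_conv(feature, weights) - ref).max() < 1e-12

    def test_separable_pair_equals_rank_one_full_convolution(self, rng):
        # depthwise(k_c) followed by pointwise(W) is the full convolution
        # with kernel K[k, c] = W[k, c] · k_c
        from histoseg._autodiff import im2col_conv2d

        feature = rng.normal(0, 1, (6, 6, 3))
        kernels = rng.normal(0, 1, (3, 3, 3))
        weights = rng.normal(0, 1, (2, 3))
        sep = pointwise_conv(depthwise_conv(feature, kernels, 1, 1), weights)
        full_kernel = np.einsum("kc,ijc->kcij", weights, kernels)
        full = im2col_conv2d(
            feature.transpose(2, 0, 1)[None], full_kernel, stride=1, pad=1
        )[0].transpose(1, 2, 0)
        assert np.abs(sep - full).max() < 1e-9


class TestInvertedResidual:
    def test_pure_residual_with_zero_weights(self, rng):
        block = InvertedResidual(4, expansion=1, out_ch=4, stride=1)
        for p in block.parameters():
            p.data[:] = 0.0
        block.eval()
        x = Tensor(rng.normal(0, 1, (2, 4, 6, 6)).astype(np.float32))
        out = block(x)
        assert np.allclose(out.data, x.data)

    def test_stride_two_halves_resolution(self, rng):
        block = InvertedResidual(8, expansion=6, out_ch=16, stride=2)
        x = Tensor(rng.normal(0, 1, (1, 8, 56, 56)).astype(np.float32))
        assert block(x).shape == (1, 16, 28, 28)

    def test_parameter_count_closed_form(self):
        in_ch, t, out_ch = 8, 6, 16
        block = InvertedResidual(in_ch, t, out_ch, stride=1)
        hidden = in_ch * t
        expected = (
            in_ch * hidden  # expansion 1×1
            + 2 * hidden  # its batch-norm affine
            + hidden * 9  # depthwise 3×3
            + 2 * hidden
            + hidden * out_ch  # projection 1×1
            + 2 * out_ch
        )
        assert block.parameter_count() == expected


class TestModel:
    def test_tiny_forward_probabilities(self, rng):
        model = build_model(EncoderConfig(input_size=64, width_multiplier=0.25), seed=0)
        x = rng.normal(0, 1, (2, 64, 64, 3)).astype(np.float32)
        probs = segment(model, x)
        assert probs.shape == (2, 64, 64, 2)
        assert np.abs(probs.sum(axis=-1) - 1).max() < 1e-5

    def test_identical_inputs_give_identical_maps(self, rng):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=0)
        x = rng.normal(0, 1, (32, 32, 3)).astype(np.float32)
        probs = segment(model, np.stack([x, x]))
        assert (probs[0] == probs[1]).all()

    def test_evaluation_mode_is_deterministic(self, rng):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=0)
        x = rng.normal(0, 1, (1, 32, 32, 3)).astype(np.float32)
        assert (segment(model, x) == segment(model, x)).all()

    def test_indivisible_input_rejected(self, rng):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=0)
        with pytest.raises(ValueError, match="divisible by 32"):
            segment(model, rng.normal(0, 1, (1, 33, 33, 3)).astype(np.float32))

    def test_classify_probabilities(self, rng):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=0)
        x = rng.normal(0, 1, (32, 32, 3)).astype(np.float32)
        probs = classify(model, x)
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zeroed_head_gives_uniform_probabilities(self, rng):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=0)
        model.fc_out.weight.data[:] = 0.0
        model.fc_out.bias.data[:] = 0.0
        probs = classify(model, rng.normal(0, 1, (32, 32, 3)).astype(np.float32))
        assert np.allclose(probs, 0.5, atol=1e-6)

    def test_grad_cam_zero_gradients_give_zero_map(self, rng):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=0)
        model.fc_out.weight.data[:] = 0.0
        model.fc_hidden.weight.data[:] = 0.0
        heat = grad_cam(model, rng.normal(0, 1, (32, 32, 3)).astype(np.float32), target=0)
        assert heat.shape == (32, 32)
        assert (heat == 0).all()

    def test_grad_cam_range_and_undefined_class(self, rng):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=0)
        x = rng.normal(0, 1, (32, 32, 3)).astype(np.float32)
        heat = grad_cam(model, x, target=1)
        assert heat.min() >= 0 and heat.max() <= 1
        with pytest.raises(ValueError, match="class id"):
            grad_cam(model, x, target=5)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = build_model(EncoderConfig(input_size=32, width_multiplier=0.1), seed=3)
        x = rng.normal(0, 1, (1, 32, 32, 3)).astype(np.float32)
        before = segment(model, x)
        save_model(model, tmp_path / "ckpt")
        restored = load_model(tmp_path / "ckpt")
        assert (segment(restored, x) == before).all()

    def test_width_multiplier_scales_parameters(self):
        small = count_parameters(build_model(EncoderConfig(input_size=32, width_multiplier=0.1)))
        big = count_parameters(build_model(EncoderConfig(input_size=32, width_multiplier=0.25)))
        assert small < big
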