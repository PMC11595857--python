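"""Separable-convolution primitives, residual blocks, and model assembly."""

import numpy as np
import pytest

from esanet import nn
from esanet.backbone import (ArchitectureSpec, ConvSpec, build_esa_resnet34,
                             build_reference_model, depthwise_conv2d,
                             layer_signature, make_ds_block, pointwise_conv2d)


def naive_conv2d(x, w, stride=1, padding=0, groups=1):
    """Quadruple-loop direct convolution oracle (independent of the package)."""
    n, cin, h, wd = x.shape
    cout, cg, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wd + 2 * padding - k) // stride + 1
    og = cout // groups
    y = np.zeros((n, cout, ho, wo))
    for b in range(n):
        for o in range(cout):
            g = o // og
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for c in range(cg):
                        for ki in range(k):
                            for kj in range(k):
                                acc += (w[o, c, ki, kj]
                                        * xp[b, g * cg + c,
                                             i * stride + ki, j * stride + kj])
                    y[b, o, i, j] = acc
    return y


class TestDepthwise:
    def test_identity_kernel(self, rng):
        x = rng.normal(size=(2, 3, 5, 5)).astype(np.float32)
        kernels = np.zeros((3, 3, 3), dtype=np.float32)
        kernels[:, 1, 1] = 1.0  # Kronecker delta at the center
        y = depthwise_conv2d(x, kernels, stride=1, padding=1)
        np.testing.assert_allclose(y, x, atol=1e-6)

    def test_channel_count_preserved(self, rng):
        x = rng.normal(size=(4, 64, 8, 8)).astype(np.float32)
        y = depthwise_conv2d(x, rng.normal(size=(64, 3, 3)), padding=1)
        assert y.shape == (4, 64, 8, 8)

    @pytest.mark.parametrize("stride,padding", [(1, 1), (2, 1), (1, 0)])
    def test_matches_naive_loop_oracle(self, rng, stride, padding):
        for _ in range(10):
            x = rng.integers(-3, 4, size=(1, 2, 4, 4)).astype(np.float32)
            k = rng.normal(size=(2, 3, 3)).astype(np.float32)
            got = depthwise_conv2d(x, k, stride=stride, padding=padding)
            want = naive_conv2d(x, k.reshape(2, 1, 3, 3), stride, padding, groups=2)
            np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)

    def test_channel_independence(self, rng):
        """Perturbing input channel i changes only output channel i."""
        x = rng.normal(size=(1, 5, 6, 6)).astype(np.float32)
        k = rng.normal(size=(5, 3, 3)).astype(np.float32)
        base = depthwise_conv2d(x, k, padding=1)
        x2 = x.copy()
        x2[0, 2] += 1.0
        pert = depthwise_conv2d(x2, k, padding=1)
        changed = np.array([np.any(pert[0, c] != base[0, c]) for c in range(5)])
        assert changed[2] and not changed[[0, 1, 3, 4]].any()

    def test_filter_count_mismatch_rejected(self, rng):
        x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        with pytest.raises(ValueError, match="one filter per input channel"):
            depthwise_conv2d(x, rng.normal(size=(3, 3, 3)))


class TestPointwise:
    def test_identity_mixing(self, rng):
        x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(pointwise_conv2d(x, np.eye(4)), x, atol=1e-6)

    def test_forced_linear_combination(self):
        x = np.array([2.0, 3.0, 5.0]).reshape(1, 3, 1, 1)
        mix = np.array([[1, 0, 0], [0, 1, 1]], dtype=float)
        y = pointwise_conv2d(x, mix)
        np.testing.assert_allclose(y.ravel(), [2.0, 8.0])

    def test_matches_per_pixel_matmul_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
            mix = rng.normal(size=(5, 3)).astype(np.float32)
            got = pointwise_conv2d(x, mix)
            want = np.einsum("oc,nchw->nohw", mix, x)
            np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)
            assert got.shape == (2, 5, 4, 4)  # spatial dims untouched

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            pointwise_conv2d(np.ones((1, 3, 2, 2), np.float32), np.eye(4))


class TestSeparableEquivalence:
    def test_rank_one_filters_reproduce_standard_conv(self, rng):
        """depthwise d then pointwise m == standard conv with w[o,c] = m[o,c]·d[c]."""
        cin, cout = 3, 4
        x = rng.normal(size=(2, cin, 6, 6)).astype(np.float32)
        d = rng.normal(size=(cin, 3, 3)).astype(np.float32)
        m = rng.normal(size=(cout, cin)).astype(np.float32)
        sep = pointwise_conv2d(depthwise_conv2d(x, d, padding=1), m)
        w = np.einsum("oc,ckl->ockl", m, d)
        std = naive_conv2d(x.astype(np.float64), w.astype(np.float64),
                           stride=1, padding=1)
        np.testing.assert_allclose(sep, std, rtol=1e-4, atol=1e-4)


class TestBlocks:
    def test_stride1_preserves_shape(self, small_arch, rng):
        blk = make_ds_block(16, 16, 1, small_arch)
        x = rng.normal(size=(2, 16, 8, 8)).astype(np.float32)
        assert blk(x).shape == (2, 16, 8, 8)

    def test_stride2_downsamples(self, rng):
        spec = ArchitectureSpec()
        blk = make_ds_block(64, 128, 2, spec)
        x = rng.normal(size=(1, 64, 56, 56)).astype(np.float32)
        assert blk(x).shape == (1, 128, 28, 28)

    def test_invalid_stride_rejected(self, small_arch):
        with pytest.raises(ValueError, match="stride"):
            make_ds_block(8, 8, 3, small_arch)

    def test_separable_block_body_parameter_count(self):
        """Closed form k·k·C + C·C' per separable conv; 2 convs per block."""
        spec = ArchitectureSpec(use_esa=False, dropout_rate=0.0)
        blk = make_ds_block(64, 64, 1, spec)
        conv_params = sum(
            p.size for name, p in blk.named_parameters()
            if p.value.ndim == 4)
        assert conv_params == 2 * (3 * 3 * 64 + 64 * 64) == 9344
        std = ArchitectureSpec(use_esa=False, use_depthwise=False,
                               dropout_rate=0.0)
        std_blk = make_ds_block(64, 64, 1, std)
        std_params = sum(p.size for _, p in std_blk.named_parameters()
                         if p.value.ndim == 4)
        assert std_params == 2 * 3 * 3 * 64 * 64 == 73728


class TestAssembly:
    def test_forward_logits_shape(self, small_arch, rng):
        model = build_esa_resnet34(small_arch)
        x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
        assert model(x).shape == (2, 5)

    def test_full_scale_forward(self, rng):
        model = build_esa_resnet34(ArchitectureSpec()).eval()
        x = rng.normal(size=(1, 3, 224, 224)).astype(np.float32)
        assert model(x).shape == (1, 61)

    def test_total_downsampling_factor_32(self, small_arch):
        model = build_esa_resnet34(small_arch)
        # shape right before global pooling: input 64x64 -> 2x2
        shape = (1, 3, 64, 64)
        for m in model:
            if isinstance(m, nn.GlobalAvgPool):
                break
            shape = m.out_shape(shape)
        assert shape[2:] == (64 // 32, 64 // 32)

    def test_all_flags_off_is_standard_resnet34(self):
        plain = build_esa_resnet34(ArchitectureSpec(
            use_esa=False, use_depthwise=False, dropout_rate=0.0))
        ref = build_reference_model("resnet34", 61)
        assert layer_signature(plain) == layer_signature(ref)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="doubling"):
            build_esa_resnet34(ArchitectureSpec(stage_widths=(64, 128, 256, 256)))
        with pytest.raises(ValueError, match=">= 1"):
            build_esa_resnet34(ArchitectureSpec(stage_block_counts=(0, 4, 6, 3)))
        with pytest.raises(ValueError, match="num_classes"):
            build_esa_resnet34(ArchitectureSpec(num_classes=1))
        with pytest.raises(ValueError, match="dropout_rate"):
            build_esa_resnet34(ArchitectureSpec(dropout_rate=1.0))

    def test_spec_round_trips_through_dict(self, small_arch):
        d = small_arch.to_dict()
        assert ArchitectureSpec.from_dict(d) == small_arch


class TestReferenceModels:
    def test_unknown_name_lists_valid_names(self):
        with pytest.raises(ValueError, match="resnet34"):
            build_reference_model("lenet", 61)

    @pytest.mark.parametrize("name,known_1000", [
        ("resnet18", 11_689_512),
        ("mobilenet", 3_504_872),
    ])
    def test_canonical_parameter_totals(self, name, known_1000):
        model = build_reference_model(name, 1000)
        assert sum(p.size for p in model.parameters()) == known_1000

    def test_head_resizing_arithmetic(self):
        """Param difference between 1000- and 61-class heads is (in+1)*939."""
        big = build_reference_model("resnet18", 1000)
        small = build_reference_model("resnet18", 61)
        diff = (sum(p.size for p in big.parameters())
                - sum(p.size for p in small.parameters()))
        assert diff == (512 + 1) * 939


class TestConvSpec:
    def test_depthwise_and_pointwise_predicates(self):
        assert ConvSpec(8, 8, 3, groups=8).is_depthwise
        assert ConvSpec(8, 16, 1).is_pointwise
        assert not ConvSpec(8, 16, 3).is_depthwise

    def test_groups_must_divide_channels(self):
        with pytest.raises(ValueError, match="divide"):
            ConvSpec(6, 6, 3, groups=4)
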