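"""Diverse branch block: branch arithmetic and exact reparameterization."""

import numpy as np
import pytest

from dualmatch import dbb, nn
from dualmatch.nn import Tensor


def naive_conv2d(x, w, b=None, stride=1, pad=0):
    """Loop-based valid convolution oracle (zero padding)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, wd = x.shape
    d, _, kh, kw = w.shape
    ho = (h - kh) // stride + 1
    wo = (wd - kw) // stride + 1
    out = np.zeros((n, d, ho, wo))
    for ni in range(n):
        for di in range(d):
            for i in range(ho):
                for j in range(wo):
                    patch = x[ni, :, i * stride:i * stride + kh,
                              j * stride:j * stride + kw]
                    out[ni, di, i, j] = (patch * w[di]).sum()
            if b is not None:
                out[ni, di] += b[di]
    return out


def randomize_bn(block, rng):
    for bn in (block.bn1, block.bn2, block.bn3, block.bn4, block.bn5, block.bn6):
        d = len(bn.running_mean)
        bn.running_mean = rng.normal(0, 1, d).astype(np.float32)
        bn.running_var = rng.uniform(0.5, 2.0, d).astype(np.float32)
        bn.gamma.data = rng.uniform(0.5, 1.5, d).astype(np.float32)
        bn.beta.data = rng.normal(0, 1, d).astype(np.float32)


class TestFuseBN:
    def test_identity_bn_leaves_kernel_unchanged(self, rng):
        w = rng.normal(0, 1, (4, 3, 3, 3)).astype(np.float32)
        f, b = dbb.fuse_bn(w, np.ones(4), np.ones(4), np.zeros(4), np.zeros(4))
        np.testing.assert_array_equal(f, w)
        np.testing.assert_array_equal(b, 0)

    def test_formula_example(self):
        w = np.ones((1, 1, 1, 1), dtype=np.float32)
        f, b = dbb.fuse_bn(w, gamma=np.array([2.0]), sigma=np.array([1.0]),
                           mu=np.array([1.0]), beta=np.array([0.0]))
        assert f[0, 0, 0, 0] == 2.0 and b[0] == -2.0

    def test_conv_then_bn_equals_fused_conv(self, rng):
        w = rng.normal(0, 1, (4, 3, 3, 3)).astype(np.float32)
        gamma = rng.uniform(0.5, 1.5, 4)
        sigma = rng.uniform(0.5, 2.0, 4)
        mu = rng.normal(0, 1, 4)
        beta = rng.normal(0, 1, 4)
        x = rng.normal(0, 1, (2, 3, 8, 8))
        raw = naive_conv2d(x, w)
        bn_out = gamma[:, None, None] / sigma[:, None, None] \
            * (raw - mu[:, None, None]) + beta[:, None, None]
        f, b = dbb.fuse_bn(w, gamma, sigma, mu, beta)
        np.testing.assert_allclose(naive_conv2d(x, f, b), bn_out, atol=1e-5)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            dbb.fuse_bn(np.ones((1, 1, 1, 1)), np.ones(1), np.zeros(1),
                        np.zeros(1), np.zeros(1))


class TestMergeSequential:
    def test_identity_pointwise_returns_spatial(self, rng):
        f_spatial = rng.normal(0, 1, (3, 3, 3, 3)).astype(np.float32)
        eye = np.eye(3, dtype=np.float32).reshape(3, 3, 1, 1)
        np.testing.assert_allclose(dbb.merge_sequential(eye, f_spatial),
                                   f_spatial, atol=1e-7)

    def test_center_delta_spatial_broadcasts_pointwise(self, rng):
        f_point = rng.normal(0, 1, (2, 3, 1, 1)).astype(np.float32)
        delta = np.zeros((2, 2, 3, 3), dtype=np.float32)
        delta[0, 0, 1, 1] = delta[1, 1, 1, 1] = 2.5
        merged = dbb.merge_sequential(f_point, delta)
        np.testing.assert_allclose(merged[:, :, 1, 1], 2.5 * f_point[:, :, 0, 0],
                                   atol=1e-6)
        merged[:, :, 1, 1] = 0
        assert np.all(merged == 0)

    def test_composition_equals_merged_kernel(self, rng):
        f_point = rng.normal(0, 1, (4, 3, 1, 1)).astype(np.float32)
        f_spatial = rng.normal(0, 1, (5, 4, 3, 3)).astype(np.float32)
        x = rng.normal(0, 1, (2, 3, 9, 9))
        composed = naive_conv2d(naive_conv2d(x, f_point), f_spatial)
        merged = naive_conv2d(x, dbb.merge_sequential(f_point, f_spatial))
        np.testing.assert_allclose(composed, merged, atol=1e-4)


class TestAvgPoolAsConv:
    def test_k1_is_identity(self, rng):
        kern = dbb.avgpool_as_conv(3, 1)
        x = rng.normal(0, 1, (1, 3, 5, 5))
        np.testing.assert_allclose(naive_conv2d(x, kern), x, atol=1e-6)

    def test_constant_input_preserved(self):
        kern = dbb.avgpool_as_conv(2, 3)
        x = np.full((1, 2, 7, 7), 1.7)
        np.testing.assert_allclose(naive_conv2d(x, kern), 1.7, atol=1e-6)

    def test_matches_sliding_window_mean(self, rng):
        kern = dbb.avgpool_as_conv(1, 3)
        x = rng.normal(0, 1, (1, 1, 7, 7))
        out = naive_conv2d(x, kern)
        for i in range(5):
            for j in range(5):
                assert out[0, 0, i, j] == pytest.approx(
                    x[0, 0, i:i + 3, j:j + 3].mean(), abs=1e-6)


class TestForward:
    def test_zero_kernels_zero_beta_give_zero_output(self, rng):
        blk = dbb.DBBBlock(2, 3, 3, rng=rng)
        for f in (blk.f1, blk.f2, blk.f3, blk.f4, blk.f6):
            f.data[:] = 0
        out = blk.forward(Tensor(rng.normal(0, 1, (1, 2, 6, 6))), training=False)
        np.testing.assert_allclose(out.data, 0, atol=1e-6)

    def test_single_branch_identity_bn_is_plain_convolution(self, rng):
        blk = dbb.DBBBlock(2, 3, 3, rng=rng)
        for f in (blk.f1, blk.f2, blk.f3, blk.f4):
            f.data[:] = 0
        x = rng.normal(0, 1, (2, 2, 6, 6))
        out = blk.forward(Tensor(x), training=False)
        oracle = naive_conv2d(x, blk.f6.data, stride=1, pad=1)
        np.testing.assert_allclose(out.data, oracle, atol=1e-4)

    def test_matches_per_branch_naive_oracle(self, rng):
        blk = dbb.DBBBlock(3, 4, 3, stride=1, rng=rng)
        randomize_bn(blk, rng)
        x = rng.normal(0, 1, (2, 3, 7, 7))
        out = blk.forward(Tensor(x), training=False).data

        def bn_apply(y, bn):
            inv = 1 / np.sqrt(bn.running_var.astype(float) + bn.eps)
            return bn.gamma.data[:, None, None] * (y - bn.running_mean[:, None, None]) \
                * inv[:, None, None] + bn.beta.data[:, None, None]

        def pad_with_value(y, value):
            n, c, h, w = y.shape
            out = np.empty((n, c, h + 2, w + 2), dtype=y.dtype)
            out[...] = value[None, :, None, None]
            out[:, :, 1:-1, 1:-1] = y
            return out

        def bias_at_zero(bn):
            return bn.beta.data - bn.running_mean * bn.gamma.data \
                / np.sqrt(bn.running_var.astype(float) + bn.eps)

        b1 = bn_apply(naive_conv2d(x, blk.f1.data), blk.bn1)
        mid2 = bn_apply(naive_conv2d(x, blk.f2.data), blk.bn2)
        b2 = bn_apply(naive_conv2d(pad_with_value(mid2, bias_at_zero(blk.bn2)),
                                   blk.f3.data), blk.bn3)
        mid4 = bn_apply(naive_conv2d(x, blk.f4.data), blk.bn4)
        b3 = bn_apply(naive_conv2d(pad_with_value(mid4, bias_at_zero(blk.bn4)),
                                   blk._avg.data), blk.bn5)
        b4 = bn_apply(naive_conv2d(x, blk.f6.data, pad=1), blk.bn6)
        np.testing.assert_allclose(out, b1 + b2 + b3 + b4, atol=1e-4)

    def test_channel_mismatch_rejected(self, rng):
        blk = dbb.DBBBlock(3, 4, 3, rng=rng)
        with pytest.raises(ValueError):
            blk.forward(Tensor(np.zeros((1, 2, 6, 6))))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            dbb.DBBBlock(2, 2, 4)


class TestReparameterize:
    def test_single_branch_identity_bn_returns_f6(self, rng):
        blk = dbb.DBBBlock(2, 3, 3, rng=rng)
        for f in (blk.f1, blk.f2, blk.f3, blk.f4):
            f.data[:] = 0
        rc = dbb.reparameterize(blk)
        np.testing.assert_allclose(rc.weight.data, blk.f6.data, atol=1e-5)
        np.testing.assert_allclose(rc.bias.data, 0, atol=1e-5)

    def test_zero_block_bias_is_sum_of_bn_shifts(self, rng):
        blk = dbb.DBBBlock(2, 3, 3, rng=rng)
        for f in (blk.f1, blk.f2, blk.f3, blk.f4, blk.f6):
            f.data[:] = 0
        for bn in (blk.bn1, blk.bn2, blk.bn3, blk.bn4, blk.bn5, blk.bn6):
            bn.beta.data = rng.normal(0, 1, 3).astype(np.float32)
        rc = dbb.reparameterize(blk)
        np.testing.assert_allclose(rc.weight.data, 0, atol=1e-7)
        # zero kernels: the branch-final BN shifts survive, and the pooling
        # branch additionally carries its 1x1 stage's shift through the
        # average pool (scaled by BN5's gamma/sigma)
        scale5 = blk.bn5.gamma.data / np.sqrt(blk.bn5.running_var + blk.bn5.eps)
        expected = (blk.bn1.beta.data + blk.bn3.beta.data
                    + scale5 * blk.bn4.beta.data + blk.bn5.beta.data
                    + blk.bn6.beta.data)
        np.testing.assert_allclose(rc.bias.data, expected, atol=1e-5)

    def test_equivalence_over_random_configurations(self):
        from dualmatch.cli import reparam_deviation
        assert reparam_deviation(seed=0, n_blocks=20) < 1e-4

    def test_homogeneity_scaling_kernels_scales_reparam(self, rng):
        blk = dbb.DBBBlock(2, 3, 3, rng=rng)
        randomize_bn(blk, rng)
        for bn in (blk.bn1, blk.bn2, blk.bn3, blk.bn4, blk.bn5, blk.bn6):
            bn.running_mean[:] = 0
            bn.beta.data[:] = 0
        base = dbb.reparameterize(blk)
        for f in (blk.f1, blk.f2, blk.f4, blk.f6):
            f.data *= 2.0  # sequential branches stay linear in one factor
        scaled = dbb.reparameterize(blk)
        np.testing.assert_allclose(scaled.weight.data, 2 * base.weight.data,
                                   atol=1e-4)

    def test_additivity_sum_of_blocks_equals_sum_of_kernels(self, rng):
        a = dbb.DBBBlock(2, 3, 3, rng=rng)
        b = dbb.DBBBlock(2, 3, 3, rng=np.random.default_rng(7))
        randomize_bn(a, rng)
        randomize_bn(b, rng)
        x = Tensor(rng.normal(0, 1, (2, 2, 6, 6)).astype(np.float32))
        summed = a.forward(x, training=False).data + b.forward(x, training=False).data
        ra, rb = dbb.reparameterize(a), dbb.reparameterize(b)
        merged = dbb.ReparamConv(ra.weight.data + rb.weight.data,
                                 ra.bias.data + rb.bias.data, 1, 1)
        np.testing.assert_allclose(merged.forward(x).data, summed, atol=1e-4)


class TestTargetNetwork:
    def test_resnet18_style_kernel_count(self):
        net = dbb.build_target_network({"backbone": "resnet18"})
        assert dbb.count_feature_channels(net) == 3904

    def test_toy_kernel_counts(self):
        one = dbb.ToyDBBNet(widths=(4, 8), blocks_per_stage=1)
        assert dbb.count_feature_channels(one) == 12
        two = dbb.ToyDBBNet(widths=(8, 16, 32, 64))
        assert dbb.count_feature_channels(two) == 240
        single = dbb.ToyDBBNet(widths=(5,), blocks_per_stage=1)
        assert dbb.count_feature_channels(single) == 5

    def test_forward_returns_class_logits(self, rng):
        net = dbb.build_target_network({"backbone": "toy", "widths": (4, 8),
                                        "n_classes": 3})
        x = Tensor(rng.normal(0, 1, (2, 3, 32, 32)).astype(np.float32))
        assert net.forward(x).shape == (2, 3)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            dbb.build_target_network({"backbone": "vgg"})

    def test_network_reparameterization_is_equivalent(self, rng):
        net = dbb.ToyDBBNet(widths=(4, 8), seed=1)
        x = Tensor(rng.normal(0, 1, (4, 3, 32, 32)).astype(np.float32))
        net.forward(x, training=True)  # populate running statistics
        y_train = net.forward(x, training=False).data
        y_rep = net.reparameterize().forward(x).data
        np.testing.assert_allclose(y_train, y_rep, atol=1e-4)
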