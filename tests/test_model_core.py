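"""Attention operators vs straight-line oracles, block contracts, ablations."""

import numpy as np
import pytest

from ecgcoattn.autodiff import Tensor
from ecgcoattn.layers import Conv2d
from ecgcoattn.model_core import (
    ChannelAttention, CoAttentionECGNet, LTCARBlock, ModelConfig,
    MultiScaleBranches, SpatialAttention, build_model, count_params,
)
from ecgcoattn.train_loop import he_init


def channel_attention_oracle(x, w1, b1, w2, b2):
    """Literal squeeze-and-excitation arithmetic: GAP, two 1x1 maps,
    ReLU/sigmoid, channel-wise rescale."""
    n, c = x.shape[:2]
    s = x.mean(axis=(2, 3))                                   # (N, C)
    h = np.maximum(s @ w1 + b1, 0.0)
    wgt = 1.0 / (1.0 + np.exp(-(h @ w2 + b2)))
    return x * wgt[:, :, None, None], wgt


def spatial_attention_oracle(x, kernel_w, kernel_b, k):
    """Literal spatial gate: channel max/mean maps, dense same-padded
    correlation, sigmoid, elementwise rescale."""
    n, c, leads, t = x.shape
    mx = x.max(axis=1)
    av = x.mean(axis=1)
    stacked = np.stack([mx, av], axis=1)                      # (N, 2, l, T)
    pad = k // 2
    sp = np.pad(stacked, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    amap = np.zeros((n, leads, t))
    for b in range(n):
        for i in range(leads):
            for j in range(t):
                patch = sp[b, :, i:i + k, j:j + k]
                amap[b, i, j] = (patch * kernel_w[0]).sum() + kernel_b[0]
    wgt = 1.0 / (1.0 + np.exp(-amap))
    return x * wgt[:, None, :, :], wgt


class TestChannelAttention:
    def test_matches_oracle_on_random_tensors(self, rng):
        att = ChannelAttention(4, 2)
        att.fc1.weight.data = rng.normal(size=(4, 2)).astype(np.float32)
        att.fc1.bias.data = rng.normal(size=2).astype(np.float32)
        att.fc2.weight.data = rng.normal(size=(2, 4)).astype(np.float32)
        att.fc2.bias.data = rng.normal(size=4).astype(np.float32)
        for _ in range(20):
            x = rng.normal(size=(1, 4, 3, 8)).astype(np.float32)
            ours = att(Tensor(x)).data
            expect, wgt = channel_attention_oracle(
                x, att.fc1.weight.data, att.fc1.bias.data,
                att.fc2.weight.data, att.fc2.bias.data)
            np.testing.assert_allclose(ours, expect, atol=1e-5)
            assert ((wgt > 0) & (wgt < 1)).all()

    def test_zero_weights_halve_input(self, rng):
        att = ChannelAttention(6, 2)
        for p in (att.fc1.weight, att.fc1.bias, att.fc2.weight, att.fc2.bias):
            p.data[:] = 0.0
        x = rng.normal(size=(2, 6, 4, 10)).astype(np.float32)
        np.testing.assert_array_equal(att(Tensor(x)).data, 0.5 * x)

    def test_ratio_constant_within_channel(self, rng):
        att = ChannelAttention(3, 2)
        x = rng.normal(size=(2, 3, 4, 6)).astype(np.float32) + 5.0
        ratio = att(Tensor(x)).data / x
        for b in range(2):
            for c in range(3):
                vals = ratio[b, c]
                assert np.ptp(vals) < 1e-6


class TestSpatialAttention:
    def test_matches_oracle_on_random_tensors(self, rng):
        att = SpatialAttention(kernel=3)
        att.conv.weight.data = rng.normal(
            size=att.conv.weight.data.shape).astype(np.float32)
        att.conv.bias.data = rng.normal(size=1).astype(np.float32)
        for _ in range(10):
            x = rng.normal(size=(1, 3, 4, 6)).astype(np.float32)
            ours = att(Tensor(x)).data
            expect, wgt = spatial_attention_oracle(
                x, att.conv.weight.data, att.conv.bias.data, 3)
            np.testing.assert_allclose(ours, expect, atol=1e-5)
            assert ((wgt > 0) & (wgt < 1)).all()

    def test_zero_weights_halve_input(self, rng):
        att = SpatialAttention(7)
        att.conv.weight.data[:] = 0.0
        att.conv.bias.data[:] = 0.0
        x = rng.normal(size=(2, 3, 12, 20)).astype(np.float32)
        np.testing.assert_array_equal(att(Tensor(x)).data, 0.5 * x)

    def test_gate_shape_independent_of_channels(self, rng):
        att = SpatialAttention(3)
        for c in (1, 3, 8):
            x = Tensor(rng.normal(size=(2, c, 5, 9)).astype(np.float32))
            assert att.weights(x).shape == (2, 1, 5, 9)
            assert att(x).shape == x.shape


class TestLTCARBlock:
    def test_output_shape(self, tiny_model_cfg, rng):
        block = LTCARBlock(4, 6, 3, 7, tiny_model_cfg)
        x = Tensor(rng.normal(size=(2, 4, 4, 16)).astype(np.float32))
        assert block(x).shape == (2, 6, 4, 16)

    def test_pure_skip_when_paths_zeroed(self, tiny_model_cfg, rng):
        cfg = ModelConfig(**{**tiny_model_cfg.to_dict(),
                             "use_lead_attention": False,
                             "use_temporal_attention": False})
        block = LTCARBlock(4, 4, 3, 5, cfg)
        block.eval()
        for name, p in block.named_parameters():
            if "conv" in name:
                p.data[:] = 0.0
        x = rng.normal(size=(2, 4, 3, 12)).astype(np.float32)
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-6)

    def test_gradient_reaches_input_through_skip(self, tiny_model_cfg, rng):
        block = LTCARBlock(4, 4, 1, 5, tiny_model_cfg)
        x = Tensor(rng.normal(size=(1, 4, 3, 10)).astype(np.float32),
                   requires_grad=True)
        block(x).sum().backward()
        assert x.grad is not None and np.abs(x.grad).sum() > 0


class TestMultiScale:
    def test_three_branch_concat_channels(self, tiny_model_cfg, rng):
        ms = MultiScaleBranches(tiny_model_cfg, in_ch=5)
        x = Tensor(rng.normal(size=(2, 5, 4, 16)).astype(np.float32))
        assert ms(x).shape == (2, 3 * tiny_model_cfg.branch_channels, 4, 16)

    def test_single_branch_keeps_middle_width(self, tiny_model_cfg, rng):
        cfg = ModelConfig(**{**tiny_model_cfg.to_dict(), "n_branches": 1})
        ms = MultiScaleBranches(cfg, in_ch=5)
        assert [b.width for b in ms.branches] == [7]
        x = Tensor(rng.normal(size=(2, 5, 4, 16)).astype(np.float32))
        assert ms(x).shape == (2, cfg.branch_channels, 4, 16)

    def test_branch_order_fixes_channel_blocks(self, tiny_model_cfg, rng):
        ms = MultiScaleBranches(tiny_model_cfg, in_ch=5)
        ms.eval()
        x = Tensor(rng.normal(size=(1, 5, 4, 16)).astype(np.float32))
        full = ms(x).data
        bc = tiny_model_cfg.branch_channels
        for i, branch in enumerate(ms.branches):
            branch.eval()
            solo = branch(x).data
            np.testing.assert_allclose(full[:, i * bc:(i + 1) * bc], solo,
                                       atol=1e-6)


class TestClassifierHead:
    def test_gap_of_constant_map(self, tiny_model_cfg, rng):
        from ecgcoattn.model_core import ClassifierHead
        head = ClassifierHead(tiny_model_cfg, in_ch=4)
        head.eval()
        x = np.ones((2, 4, 3, 8), dtype=np.float32) * \
            np.arange(1, 5, dtype=np.float32)[None, :, None, None]
        # with the first linear as identity rows, pooled values pass through
        logits = head(Tensor(x))
        assert logits.shape == (2, tiny_model_cfg.n_classes)

    def test_head_matches_dense_arithmetic(self, rng):
        from ecgcoattn.model_core import ClassifierHead
        from scipy.special import erf
        cfg = ModelConfig(n_leads=2, input_len=16, n_classes=2,
                          head_hidden=3, dropout_p=0.0)
        head = ClassifierHead(cfg, in_ch=2)
        head.eval()
        for p in (head.fc1.weight, head.fc1.bias, head.fc2.weight,
                  head.fc2.bias):
            p.data = rng.normal(size=p.data.shape).astype(np.float32)
        x = rng.normal(size=(1, 2, 2, 2)).astype(np.float32)
        got = head(Tensor(x)).data
        pooled = x.mean(axis=(2, 3))
        h = pooled @ head.fc1.weight.data + head.fc1.bias.data
        # eval-mode batch norm with fresh running stats: (h - 0) / sqrt(1+eps)
        h = h / np.sqrt(1.0 + head.bn.eps)
        h = h * 0.5 * (1.0 + erf(h / np.sqrt(2.0)))
        expect = h @ head.fc2.weight.data + head.fc2.bias.data
        np.testing.assert_allclose(got, expect, atol=1e-5)


class TestFullModel:
    def test_logit_shape_and_eval_determinism(self, tiny_model_cfg, rng):
        model = he_init(build_model(tiny_model_cfg), seed=0).eval()
        x = rng.normal(size=(2, 1, 4, 64)).astype(np.float32)
        a = model(x).data
        b = model(x).data
        assert a.shape == (2, 3)
        np.testing.assert_array_equal(a, b)

    def test_batch_permutation_equivariance(self, tiny_model_cfg, rng):
        model = he_init(build_model(tiny_model_cfg), seed=0).eval()
        x = rng.normal(size=(4, 1, 4, 64)).astype(np.float32)
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(model(x[perm]).data, model(x).data[perm],
                                   atol=1e-5)

    def test_shape_errors_name_offending_axis(self, tiny_model_cfg, rng):
        model = build_model(tiny_model_cfg)
        with pytest.raises(ValueError, match="lead"):
            model(rng.normal(size=(1, 1, 5, 64)).astype(np.float32))
        with pytest.raises(ValueError, match="time"):
            model(rng.normal(size=(1, 1, 4, 32)).astype(np.float32))
        with pytest.raises(ValueError, match="channel"):
            model(rng.normal(size=(1, 2, 4, 64)).astype(np.float32))

    def test_conv_ablation_still_classifies(self, tiny_model_cfg, rng):
        cfg = ModelConfig(**{**tiny_model_cfg.to_dict(), "use_ltcar": False})
        model = he_init(build_model(cfg), seed=0).eval()
        x = rng.normal(size=(2, 1, 4, 64)).astype(np.float32)
        assert model(x).shape == (2, 3)

    def test_no_attention_variant_has_no_gates(self, tiny_model_cfg):
        cfg = ModelConfig(**{**tiny_model_cfg.to_dict(),
                             "use_lead_attention": False,
                             "use_temporal_attention": False})
        model = build_model(cfg)
        gates = [m for m in model.modules()
                 if isinstance(m, (ChannelAttention, SpatialAttention))]
        assert gates == []


class TestCountParams:
    def test_lone_conv_arithmetic(self):
        conv = Conv2d(1, 8, (3, 15))
        assert conv.count_params() == 8 * 1 * 3 * 15 + 8

    def test_monotonic_in_head_width(self, tiny_model_cfg):
        wider = ModelConfig(**{**tiny_model_cfg.to_dict(), "head_hidden": 16})
        assert count_params(wider) > count_params(tiny_model_cfg)

    def test_invariant_to_input_length(self, tiny_model_cfg):
        longer = ModelConfig(**{**tiny_model_cfg.to_dict(), "input_len": 256})
        assert count_params(longer) == count_params(tiny_model_cfg)

    def test_reference_config_calibration_band(self):
        """The documented default configuration sits within +/-25% of the
        24.585M-parameter scale of the published full-size model."""
        n = count_params(ModelConfig())
        assert 0.75 * 24.585e6 <= n <= 1.25 * 24.585e6
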