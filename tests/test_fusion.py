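import logging

import numpy as np
import pytest

from asym.fusion import (FusionConfig, FpnFusion, GatedFusion, GateOutput,
                         ParallelFusion, PlainConcatFusion, PyramidNet,
                         UnimodalFusion, align_lengths, build_pyramid,
                         fpn_downsample, fpn_fuse, fpn_level1, gated_fusion,
                         parallel_fuse)
from asym.nn import Tensor
from asym.nn.ops import upsample_nearest


@pytest.fixture
def fus_cfg():
    return FusionConfig(model_width=6, level_width=4, dropout=0.0)


class TestFpnLevel1:
    def test_length_preserved(self, fus_cfg, rng):
        x = rng.normal(size=(8, 6))
        assert fpn_level1(x, cfg=fus_cfg).shape == (8, 6)

    def test_identity_kernel_eval_bn(self, fus_cfg, rng):
        mod = PyramidNet(fus_cfg, np.random.default_rng(0))
        mod.conv1.weight.data[:] = np.array([0.0, 1.0, 0.0], dtype=np.float32)
        mod.conv1.bias.data[:] = 0.0
        x = rng.normal(size=(9, 6)).astype(np.float32)
        out = fpn_level1(x, module=mod, training=False)
        # eval-mode BN with fresh stats divides by sqrt(1 + eps)
        np.testing.assert_allclose(out, x, atol=1e-4)

    def test_matches_sliding_window_oracle(self, fus_cfg, rng):
        mod = PyramidNet(fus_cfg, np.random.default_rng(1))
        x = rng.normal(size=(10, 6)).astype(np.float32)
        out = fpn_level1(x, module=mod, training=False)
        # independent oracle: explicit convolution loop + eval-mode BN
        w = mod.conv1.weight.data   # (C, 3) depthwise
        b = mod.conv1.bias.data
        xp = np.pad(x, ((1, 1), (0, 0)))
        conv = np.zeros_like(x)
        for t in range(10):
            for c in range(6):
                conv[t, c] = (xp[t:t + 3, c] * w[c]).sum() + b[c]
        bn = mod.bn1
        want = (conv - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) \
            * bn.gamma.data + bn.beta.data
        np.testing.assert_allclose(out, want, atol=1e-5)


class TestFpnDownsample:
    def test_500_to_250(self, fus_cfg, rng):
        x = rng.normal(size=(500, 6))
        assert fpn_downsample(x, cfg=fus_cfg).shape == (250, 6)

    def test_floor_law_odd(self, fus_cfg, rng):
        x = rng.normal(size=(7, 6))
        y = fpn_downsample(x, cfg=fus_cfg)
        assert y.shape == (3, 6)
        z = fpn_downsample(y, cfg=fus_cfg)
        assert z.shape == (1, 6)

    def test_length_one_omitted_with_warning(self, fus_cfg, rng, caplog):
        x = rng.normal(size=(1, 6))
        with caplog.at_level(logging.WARNING, logger="asym.fusion"):
            out = fpn_downsample(x, cfg=fus_cfg)
        assert out is None
        assert any("omitted" in r.message for r in caplog.records)

    def test_pool_matches_pairwise_max_oracle(self, fus_cfg):
        mod = PyramidNet(fus_cfg, np.random.default_rng(0))
        # identity conv so pooling is isolated
        mod.conv2.weight.data[:] = np.array([0.0, 1.0, 0.0], dtype=np.float32)
        mod.conv2.bias.data[:] = 0.0
        x = np.arange(36, dtype=np.float32).reshape(6, 6)
        x[::2] += 5.0   # make even rows the max of each pair
        out = fpn_downsample(x, module=mod)
        want = np.maximum(x[0::2], x[1::2])
        np.testing.assert_allclose(out, want, atol=1e-6)


class TestPyramidShapes:
    @pytest.mark.parametrize("T", list(range(4, 65)))
    def test_level_length_law(self, T, fus_cfg, rng):
        pyr = build_pyramid(rng.normal(size=(T, 6)), cfg=fus_cfg)
        assert pyr.lengths() == (T, T // 2, T // 4)


class TestUpsample:
    def test_doubling_index_map(self):
        x = Tensor(np.array([[[1.0], [2.0]]], dtype=np.float32))
        out = upsample_nearest(x, 4).data[0, :, 0]
        np.testing.assert_array_equal(out, [1.0, 1.0, 2.0, 2.0])


class TestFpnFuse:
    def test_shape(self, fus_cfg, rng):
        pa = build_pyramid(rng.normal(size=(8, 6)), cfg=fus_cfg,
                           module=PyramidNet(fus_cfg, np.random.default_rng(0)))
        pv = build_pyramid(rng.normal(size=(8, 6)), cfg=fus_cfg,
                           module=PyramidNet(fus_cfg, np.random.default_rng(1)))
        fused = fpn_fuse(pa, pv, cfg=fus_cfg)
        assert fused.features.shape == (8, 3 * fus_cfg.level_width)
        assert fused.provenance == "fpn_path"

    def test_zero_pyramids_give_bias_broadcast(self, fus_cfg):
        from asym.fusion import PyramidFeatures
        z = lambda t: np.zeros((t, 6), dtype=np.float32)
        pa = PyramidFeatures(z(8), z(4), z(2), "audio")
        pv = PyramidFeatures(z(8), z(4), z(2), "video")
        from asym.nn import Conv1d
        conv = Conv1d(12, 4, 1, np.random.default_rng(3))
        fused = fpn_fuse(pa, pv, module=conv)
        want = np.tile(conv.bias.data, 3)
        np.testing.assert_allclose(fused.features,
                                   np.tile(want, (8, 1)), atol=1e-6)

    def test_swap_invariance_with_tied_level_conv(self, fus_cfg, rng):
        # with the 1x1 conv weights tied symmetrically across the two
        # modality channel groups, swapping modalities leaves fuse output
        # unchanged
        from asym.nn import Conv1d
        conv = Conv1d(12, 4, 1, np.random.default_rng(0))
        w = conv.weight.data
        w[:, 6:, :] = w[:, :6, :]
        mod_p = PyramidNet(fus_cfg, np.random.default_rng(1))
        pa = build_pyramid(rng.normal(size=(8, 6)), cfg=fus_cfg, module=mod_p)
        pv = build_pyramid(rng.normal(size=(8, 6)), cfg=fus_cfg, module=mod_p)
        f1 = fpn_fuse(pa, pv, module=conv)
        f2 = fpn_fuse(pv, pa, module=conv)
        np.testing.assert_allclose(f1.features, f2.features, atol=1e-5)


class TestGatedFusion:
    def test_zero_logits_give_half_and_mean(self, fus_cfg, rng):
        mod = GatedFusion(fus_cfg, np.random.default_rng(0))
        mod.w_g.weight.data[:] = 0.0
        mod.w_g.bias.data[:] = 0.0
        a = rng.normal(size=(5, 6)).astype(np.float32)
        v = rng.normal(size=(5, 6)).astype(np.float32)
        out = gated_fusion(a, v, module=mod)
        np.testing.assert_allclose(out.gamma, 0.5, atol=1e-7)
        np.testing.assert_allclose(out.pre_projection, (a + v) / 2.0,
                                   atol=1e-6)

    def test_saturated_gate_passes_audio(self, fus_cfg, rng):
        mod = GatedFusion(fus_cfg, np.random.default_rng(0))
        mod.w_g.weight.data[:] = 0.0
        mod.w_g.bias.data[:] = 15.0    # sigmoid(15) ~= 1 - 3e-7
        a = rng.normal(size=(5, 6)).astype(np.float32)
        v = rng.normal(size=(5, 6)).astype(np.float32)
        out = gated_fusion(a, v, module=mod)
        np.testing.assert_allclose(out.pre_projection, a, atol=1e-4)

    def test_matches_arithmetic_oracle(self, fus_cfg, rng):
        mod = GatedFusion(fus_cfg, np.random.default_rng(2))
        a = rng.normal(size=(4, 6)).astype(np.float32)
        v = rng.normal(size=(4, 6)).astype(np.float32)
        out = gated_fusion(a, v, module=mod)
        z = np.concatenate([a, v], axis=-1).mean(axis=0)
        gamma = 1.0 / (1.0 + np.exp(-(z @ mod.w_g.weight.data
                                      + mod.w_g.bias.data)))
        pre = gamma * a + (1 - gamma) * v
        want = pre @ mod.out_proj.weight.data + mod.out_proj.bias.data
        np.testing.assert_allclose(out.gamma, gamma, atol=1e-5)
        np.testing.assert_allclose(out.fused, want, atol=1e-4)

    def test_gamma_strictly_inside_unit_interval(self, fus_cfg, rng):
        out = gated_fusion(rng.normal(size=(5, 6)), rng.normal(size=(5, 6)),
                           cfg=fus_cfg)
        assert out.gamma.min() > 0.0
        assert out.gamma.max() < 1.0
        with pytest.raises(ValueError):
            GateOutput(np.array([0.0, 0.5]), np.zeros(2), np.zeros(2))

    def test_length_mismatch_hard_error(self, fus_cfg, rng):
        mod = GatedFusion(fus_cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="equal temporal lengths"):
            mod(Tensor(rng.normal(size=(1, 4, 6)).astype(np.float32)),
                Tensor(rng.normal(size=(1, 5, 6)).astype(np.float32)))

    def test_gradient_of_pre_wrt_audio_equals_gamma(self, fus_cfg, rng):
        # finite differences on the pre-projection point
        mod = GatedFusion(fus_cfg, np.random.default_rng(4))
        a = rng.normal(size=(1, 3, 6)).astype(np.float32)
        v = rng.normal(size=(1, 3, 6)).astype(np.float32)
        _, gamma, pre0 = mod(Tensor(a), Tensor(v))
        eps = 1e-3
        a2 = a.copy()
        a2[0, 1, 2] += eps
        _, _, pre1 = mod(Tensor(a2), Tensor(v))
        # gate is computed from pooled features, so perturbation also moves
        # gamma; evaluate with the gate frozen by zeroing W_g
        mod.w_g.weight.data[:] = 0.0
        _, gamma_f, pre0 = mod(Tensor(a), Tensor(v))
        _, _, pre1 = mod(Tensor(a2), Tensor(v))
        grad = (pre1.data[0, 1, 2] - pre0.data[0, 1, 2]) / eps
        assert grad == pytest.approx(float(gamma_f.data[0, 2]), abs=1e-3)

    def test_timestep_granularity(self, rng):
        cfg = FusionConfig(model_width=6, level_width=4,
                           gate_granularity="timestep")
        mod = GatedFusion(cfg, np.random.default_rng(0))
        a = Tensor(rng.normal(size=(2, 5, 6)).astype(np.float32))
        v = Tensor(rng.normal(size=(2, 5, 6)).astype(np.float32))
        _, gamma, _ = mod(a, v)
        assert gamma.shape == (2, 5, 1)


class TestParallelFuse:
    def test_output_length_is_reference_length(self, fus_cfg, rng):
        out = parallel_fuse(rng.normal(size=(9, 6)), rng.normal(size=(9, 6)),
                            cfg=fus_cfg)
        assert out.n_steps == 9
        assert out.features.shape[-1] == 2 * fus_cfg.branch_width

    def test_ablating_a_path_halves_width(self, fus_cfg, rng):
        a = rng.normal(size=(8, 6))
        v = rng.normal(size=(8, 6))
        full = parallel_fuse(a, v, cfg=fus_cfg)
        for kw in ({"use_fpn": False}, {"use_gd": False}):
            cfg = FusionConfig(model_width=6, level_width=4, dropout=0.0, **kw)
            half = parallel_fuse(a, v, cfg=cfg)
            assert half.features.shape[-1] * 2 == full.features.shape[-1]

    def test_both_paths_disabled_rejected(self):
        cfg = FusionConfig(model_width=6, level_width=4,
                           use_fpn=False, use_gd=False)
        with pytest.raises(ValueError, match="rejected"):
            ParallelFusion(cfg, np.random.default_rng(0))

    def test_plain_concat_baseline_width(self, fus_cfg, rng):
        mod = PlainConcatFusion(fus_cfg, np.random.default_rng(0))
        a = Tensor(rng.normal(size=(1, 8, 6)).astype(np.float32))
        out = mod(a, a)
        assert out.shape == (1, 8, 2 * fus_cfg.branch_width)

    def test_composes_the_two_path_oracles(self, fus_cfg, rng):
        mod = ParallelFusion(fus_cfg, np.random.default_rng(5))
        mod.eval()
        a = rng.normal(size=(9, 6)).astype(np.float32)
        v = rng.normal(size=(9, 6)).astype(np.float32)
        got = parallel_fuse(a, v, module=mod).features
        at, vt = Tensor(a[None]), Tensor(v[None])
        fpn_part = mod.fpn(at, vt).data[0]
        gd_part = mod.gated(at, vt)[0].data[0]
        np.testing.assert_allclose(
            got, np.concatenate([fpn_part, gd_part], axis=-1), atol=1e-6)

    def test_mismatched_lengths_aligned_to_shorter(self, fus_cfg, rng):
        out = parallel_fuse(rng.normal(size=(12, 6)),
                            rng.normal(size=(8, 6)), cfg=fus_cfg)
        assert out.n_steps == 8


class TestUnimodalFusion:
    def test_width_matches_dual_path(self, fus_cfg, rng):
        mod = UnimodalFusion(fus_cfg, np.random.default_rng(0))
        mod.eval()
        x = Tensor(rng.normal(size=(1, 8, 6)).astype(np.float32))
        assert mod(x).shape == (1, 8, 2 * fus_cfg.branch_width)
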