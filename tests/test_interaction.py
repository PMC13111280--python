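import numpy as np
import pytest

from asym.interaction import (A2V, AUDIO, V2A, VIDEO, AttentionConfig,
                              AttentionMap, CoInteraction,
                              CrossModalAttention, CrossModalInteraction,
                              Frontend, MergeAligned, ModalSequence,
                              co_interact, cross_attention, frontend_project,
                              merge_aligned, scaled_dot_attention)
from asym.nn import Tensor
from asym.ssm_core import BiMambaConfig


class TestModalSequence:
    def test_valid(self):
        s = ModalSequence("a", AUDIO, np.ones((3, 2)), 1)
        assert s.n_steps == 3

    def test_rejects_bad_shapes_and_labels(self):
        with pytest.raises(ValueError):
            ModalSequence("a", AUDIO, np.ones(3))
        with pytest.raises(ValueError, match="modality"):
            ModalSequence("a", "text", np.ones((3, 2)))
        with pytest.raises(ValueError, match="label"):
            ModalSequence("a", AUDIO, np.ones((3, 2)), 2)

    def test_rejects_nonfinite_with_time_index(self):
        x = np.ones((4, 2))
        x[2, 1] = np.inf
        with pytest.raises(ValueError, match="time index 2"):
            ModalSequence("bad", VIDEO, x)


class TestFrontend:
    def test_shape(self, rng):
        x = ModalSequence("s", AUDIO, rng.normal(size=(10, 25)))
        out = frontend_project(x, 256, rng=np.random.default_rng(0))
        assert out.shape == (10, 256)

    def test_identity_initialised(self, rng):
        x = rng.normal(size=(6, 4)).astype(np.float32)
        fe = Frontend(4, 4, np.random.default_rng(0))
        fe.proj.weight.data = np.eye(4, dtype=np.float32)
        fe.proj.bias.data[:] = 0
        out = fe(Tensor(x[None])).data[0]
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_matches_matmul_oracle(self, rng):
        x = rng.normal(size=(7, 5)).astype(np.float32)
        fe = Frontend(5, 3, np.random.default_rng(1))
        out = fe(Tensor(x[None])).data[0]
        want = x @ fe.proj.weight.data + fe.proj.bias.data
        np.testing.assert_allclose(out, want, atol=1e-5)


class TestCrossAttention:
    def test_single_step(self, rng):
        cfg = AttentionConfig(n_heads=1, d_k=4)
        mod = CrossModalAttention(8, cfg, np.random.default_rng(0))
        q = rng.normal(size=(2, 1, 8)).astype(np.float32)
        c = rng.normal(size=(2, 1, 8)).astype(np.float32)
        aligned, amap = mod(Tensor(q), Tensor(c))
        assert aligned.shape == (2, 1, 8)
        np.testing.assert_allclose(amap.weights, 1.0, atol=1e-6)

    def test_identical_keys_uniform_weights(self, rng):
        cfg = AttentionConfig(n_heads=2, d_k=3)
        mod = CrossModalAttention(6, cfg, np.random.default_rng(0))
        q = rng.normal(size=(1, 4, 6)).astype(np.float32)
        c = np.tile(rng.normal(size=(1, 1, 6)).astype(np.float32), (1, 5, 1))
        aligned, amap = mod(Tensor(q), Tensor(c))
        np.testing.assert_allclose(amap.weights, 1.0 / 5, atol=1e-6)
        # aligned output equals projection of the mean value row
        _, amap2 = mod(Tensor(q), Tensor(c[:, :1]))
        aligned2, _ = mod(Tensor(q), Tensor(c[:, :1]))
        np.testing.assert_allclose(aligned.data, aligned2.data, atol=1e-5)

    def test_two_by_three_hand_oracle(self):
        # explicit softmax arithmetic with hand-set Q, K, V (d_k = 2)
        Q = np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32)
        K = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]], dtype=np.float32)
        V = np.array([[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]], dtype=np.float32)
        out, w = scaled_dot_attention(Tensor(Q), Tensor(K), Tensor(V))
        logits = Q[0] @ K[0].T / np.sqrt(2.0)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        want_w = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w.data[0], want_w, atol=1e-6)
        np.testing.assert_allclose(out.data[0], want_w @ V[0], atol=1e-6)

    def test_rows_are_probability_vectors(self, rng):
        cfg = AttentionConfig(n_heads=2, d_k=4)
        mod = CrossModalAttention(8, cfg, np.random.default_rng(0))
        q = rng.normal(size=(3, 9, 8)).astype(np.float32)
        c = rng.normal(size=(3, 13, 8)).astype(np.float32)
        _, amap = mod(Tensor(q), Tensor(c))
        amap.validate()
        assert amap.weights.shape == (3, 2, 9, 13)

    def test_permutation_equivariance_in_context(self, rng):
        cfg = AttentionConfig(n_heads=1, d_k=4)
        mod = CrossModalAttention(8, cfg, np.random.default_rng(0))
        q = rng.normal(size=(1, 5, 8)).astype(np.float32)
        c = rng.normal(size=(1, 7, 8)).astype(np.float32)
        perm = np.random.default_rng(1).permutation(7)
        a1, m1 = mod(Tensor(q), Tensor(c))
        a2, m2 = mod(Tensor(q), Tensor(c[:, perm]))
        np.testing.assert_allclose(a1.data, a2.data, atol=1e-5)
        np.testing.assert_allclose(m1.weights[..., perm], m2.weights,
                                   atol=1e-6)

    def test_functional_wrapper_and_reproducibility(self, rng):
        q = rng.normal(size=(4, 6))
        c = rng.normal(size=(5, 6))
        cfg = AttentionConfig(n_heads=2, d_k=3, direction=A2V)
        out1, m1 = cross_attention(q, c, cfg, rng=np.random.default_rng(9))
        out2, m2 = cross_attention(q, c, cfg, rng=np.random.default_rng(9))
        assert out1.shape == (4, 6)
        assert m1.direction == A2V
        # bit-for-bit reproducible given fixed parameters and input
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.mean_weight() == m2.mean_weight()


class TestMergeAligned:
    def test_zero_aligned_is_layernorm_of_ctx(self, rng):
        ctx = rng.normal(size=(3, 5)).astype(np.float32)
        mod = MergeAligned(5, np.random.default_rng(0))
        got = merge_aligned(ctx, np.zeros_like(ctx), module=mod)
        mu = ctx.mean(-1, keepdims=True)
        var = ctx.var(-1, keepdims=True)
        want = (ctx - mu) / np.sqrt(var + 1e-5)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_symmetry_when_equal(self, rng):
        a = rng.normal(size=(4, 6))
        np.testing.assert_array_equal(merge_aligned(a, a), merge_aligned(a, a))

    def test_random_case_matches_ln_sum_oracle(self, rng):
        a = rng.normal(size=(4, 6)).astype(np.float32)
        b = rng.normal(size=(4, 6)).astype(np.float32)
        got = merge_aligned(a, b)
        s = a + b
        mu = s.mean(-1, keepdims=True)
        want = (s - mu) / np.sqrt(s.var(-1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        mod = MergeAligned(6, np.random.default_rng(0))
        with pytest.raises(ValueError, match="mismatch"):
            mod(Tensor(rng.normal(size=(1, 4, 6)).astype(np.float32)),
                Tensor(rng.normal(size=(1, 5, 6)).astype(np.float32)))

    def test_concat_project_mode(self, rng):
        mod = MergeAligned(6, np.random.default_rng(0), mode="concat_project")
        a = Tensor(rng.normal(size=(1, 4, 6)).astype(np.float32))
        assert mod(a, a).shape == (1, 4, 6)


class TestCoInteract:
    def test_lengths_preserved_independently(self, rng):
        cfg = BiMambaConfig(model_width=8, state_dim=2, n_blocks=1,
                            expansion=1.0)
        a = rng.normal(size=(40, 8))
        v = rng.normal(size=(60, 8))
        oa, ov = co_interact(a, v, cfg=cfg, rng=np.random.default_rng(0))
        assert oa.shape == (40, 8)
        assert ov.shape == (60, 8)

    def test_width_mismatch_rejected(self, rng):
        cfg = BiMambaConfig(model_width=8, state_dim=2, n_blocks=1)
        mod = CoInteraction(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="width"):
            mod(Tensor(rng.normal(size=(1, 4, 8)).astype(np.float32)),
                Tensor(rng.normal(size=(1, 4, 6)).astype(np.float32)))

    def test_symmetry_probe_same_input(self, rng):
        # identical streams differ in output only through private params
        cfg = BiMambaConfig(model_width=8, state_dim=2, n_blocks=1,
                            expansion=1.0)
        mod = CoInteraction(cfg, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 16, 8)).astype(np.float32))
        oa, ov = mod(x, x)
        assert not np.allclose(oa.data, ov.data)
        # tie the private params too => outputs become identical
        ba, bv = mod.stack_audio.blocks[0], mod.stack_video.blocks[0]
        bv.in_proj.weight.data = ba.in_proj.weight.data.copy()
        bv.in_proj.bias.data = ba.in_proj.bias.data.copy()
        for sa, sv in ((ba.fwd, bv.fwd), (ba.bwd, bv.bwd)):
            sv.conv.weight.data = sa.conv.weight.data.copy()
            sv.conv.bias.data = sa.conv.bias.data.copy()
            sv.W_B.data = sa.W_B.data.copy()
            sv.W_C.data = sa.W_C.data.copy()
            sv.D_skip.data = sa.D_skip.data.copy()
        bv.out_proj.weight.data = ba.out_proj.weight.data.copy()
        bv.out_proj.bias.data = ba.out_proj.bias.data.copy()
        bv.norm.gamma.data = ba.norm.gamma.data.copy()
        bv.norm.beta.data = ba.norm.beta.data.copy()
        oa, ov = mod(x, x)
        np.testing.assert_array_equal(oa.data, ov.data)

    def test_shared_transition_gradient_flows_from_video_path(self, rng):
        cfg = BiMambaConfig(model_width=8, state_dim=2, n_blocks=1,
                            expansion=1.0)
        mod = CoInteraction(cfg, np.random.default_rng(0))
        a = Tensor(rng.normal(size=(1, 10, 8)).astype(np.float32))
        v = Tensor(rng.normal(size=(1, 10, 8)).astype(np.float32))
        _, ov = mod(a, v)
        (ov ** 2.0).mean().backward()
        shared = mod.stack_audio.blocks[0].fwd.transition
        assert shared is mod.stack_video.blocks[0].fwd.transition
        assert shared.A_log.grad is not None
        assert np.abs(shared.A_log.grad).sum() > 0


class TestFullInteraction:
    def test_shapes_and_maps(self, rng):
        cfg = BiMambaConfig(model_width=8, state_dim=2, n_blocks=1,
                            expansion=1.0)
        mod = CrossModalInteraction(5, 7, cfg, AttentionConfig(2, 4),
                                    np.random.default_rng(0))
        a = Tensor(rng.normal(size=(2, 12, 5)).astype(np.float32))
        v = Tensor(rng.normal(size=(2, 15, 7)).astype(np.float32))
        oa, ov, maps = mod(a, v)
        assert oa.shape == (2, 12, 8)
        assert ov.shape == (2, 15, 8)
        assert maps[A2V].weights.shape == (2, 2, 12, 15)
        assert maps[V2A].weights.shape == (2, 2, 15, 12)
        maps[A2V].validate()
        maps[V2A].validate()

    def test_no_attention_mode(self, rng):
        cfg = BiMambaConfig(model_width=8, state_dim=2, n_blocks=1,
                            expansion=1.0)
        mod = CrossModalInteraction(5, 7, cfg, AttentionConfig(2, 4),
                                    np.random.default_rng(0),
                                    use_attention=False)
        a = Tensor(rng.normal(size=(1, 6, 5)).astype(np.float32))
        v = Tensor(rng.normal(size=(1, 6, 7)).astype(np.float32))
        oa, ov, maps = mod(a, v)
        assert maps == {}


class TestAttentionMapStats:
    def test_identity_map_concentration_zero(self):
        w = np.tile(np.eye(6)[None], (2, 1, 1))
        amap = AttentionMap(w, A2V)
        assert amap.concentration_index() == 0.0
        assert amap.ridge_offset() == 0.0

    def test_mean_weight_is_inverse_context_length(self):
        w = np.full((1, 4, 5), 0.2)
        assert AttentionMap(w, V2A).mean_weight() == pytest.approx(0.2)
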