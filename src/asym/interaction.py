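"""Cross-modal interactive stage.

Per-modality front-end projection to a common width, a pair of Bi-Mamba
stacks whose state-transition dynamics are shared across the two
modalities, and scaled-dot-product cross-attention in both directions
(audio queries / video context and vice versa), each followed by a
residual merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import LayerNorm, Linear, Module, Tensor, concat, softmax
from .ssm_core import BiMambaConfig, BiMambaStack, make_shared_stacks

AUDIO = "audio"
VIDEO = "video"
A2V = "audio_to_video"
V2A = "video_to_audio"


@dataclass
class ModalSequence:
    """One modality's (T, F) feature matrix with provenance."""

    sample_id: str
    modality: str
    features: np.ndarray
    label: int | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: features must be a T x F matrix "
                f"with T >= 1, got shape {self.features.shape}")
        if self.modality not in (AUDIO, VIDEO):
            raise ValueError(f"sample {self.sample_id!r}: unknown modality "
                             f"{self.modality!r}")
        if not np.isfinite(self.features).all():
            t = int(np.argwhere(~np.isfinite(self.features))[0][0])
            raise ValueError(f"sample {self.sample_id!r}: non-finite feature "
                             f"at time index {t}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"sample {self.sample_id!r}: label must be 0/1, "
                             f"got {self.label!r}")

    @property
    def n_steps(self) -> int:
        return self.features.shape[0]


@dataclass
class AttentionConfig:
    n_heads: int = 2
    d_k: int = 16
    direction: str = A2V

    def __post_init__(self):
        if self.n_heads < 1 or self.d_k < 1:
            raise ValueError("n_heads and d_k must be >= 1")


@dataclass
class AttentionMap:
    """Softmax attention weights, (heads, T_q, T_k) or batched with a
    leading batch axis.  ``validate()`` checks the probability-vector
    invariants (kept out of the training hot path)."""

    weights: np.ndarray
    direction: str

    def validate(self) -> "AttentionMap":
        w = np.asarray(self.weights)
        rows = w.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("attention rows must sum to 1")
        if w.min() < -1e-7 or w.max() > 1.0 + 1e-7:
            raise ValueError("attention weights must lie in [0, 1]")
        return self

    def mean_weight(self) -> float:
        """Mean attention weight over all entries (1 / T_k for a full map)."""
        return float(self.weights.mean())

    def intensity(self) -> float:
        """Mean of the per-query maximum weight (peakedness of alignment)."""
        return float(self.weights.max(axis=-1).mean())

    def concentration_index(self) -> float:
        """Mean |query time - argmax key time| / T_k; 0 for an identity-like
        map where every query attends to its own index."""
        w = self.weights
        t_k = w.shape[-1]
        arg = w.argmax(axis=-1)
        q_idx = np.arange(w.shape[-2])
        dev = np.abs(arg - q_idx).mean()
        return float(dev / t_k)

    def ridge_offset(self) -> float:
        """Median (argmax key time - query time): the lag of the high-weight
        ridge relative to the diagonal."""
        w = self.weights
        arg = w.argmax(axis=-1)
        q_idx = np.arange(w.shape[-2])
        return float(np.median(arg - q_idx))


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor
                         ) -> tuple[Tensor, Tensor]:
    """Softmax(Q K^T / sqrt(d_k)) V over the context (key) axis.

    Q: (..., T_q, d_k), K: (..., T_k, d_k), V: (..., T_k, d_v).
    Returns (output, weights).
    """
    d_k = Q.shape[-1]
    # scale Q (small) rather than the T_q x T_k logit map (large)
    logits = (Q * (1.0 / np.sqrt(d_k))) @ K.swapaxes(-1, -2)
    weights = softmax(logits, axis=-1)
    return weights @ V, weights


class CrossModalAttention(Module):
    """Multi-head cross attention for one direction."""

    def __init__(self, model_width: int, cfg: AttentionConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.model_width = model_width
        inner = cfg.n_heads * cfg.d_k
        self.w_q = Linear(model_width, inner, rng)
        self.w_k = Linear(model_width, inner, rng)
        self.w_v = Linear(model_width, inner, rng)
        self.w_o = Linear(inner, model_width, rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        return x.reshape(B, T, self.cfg.n_heads, self.cfg.d_k).transpose(0, 2, 1, 3)

    def forward(self, query_seq: Tensor, context_seq: Tensor
                ) -> tuple[Tensor, AttentionMap]:
        if query_seq.shape[-1] != self.model_width \
                or context_seq.shape[-1] != self.model_width:
            raise ValueError("query/context width != model width")
        Q = self._split_heads(self.w_q(query_seq))
        K = self._split_heads(self.w_k(context_seq))
        V = self._split_heads(self.w_v(context_seq))
        ctx, weights = scaled_dot_attention(Q, K, V)
        B, h, Tq, dk = ctx.shape
        aligned = self.w_o(ctx.transpose(0, 2, 1, 3).reshape(B, Tq, h * dk))
        return aligned, AttentionMap(weights.data, self.cfg.direction)

    def flops(self, T: int) -> float:
        inner = self.cfg.n_heads * self.cfg.d_k
        proj = 2.0 * T * self.model_width * inner * 4
        attn = 2.0 * T * T * inner * 2  # QK^T and weights @ V
        return proj + attn


def cross_attention(query_seq: np.ndarray, context_seq: np.ndarray,
                    cfg: AttentionConfig, rng: np.random.Generator | None = None,
                    module: CrossModalAttention | None = None
                    ) -> tuple[np.ndarray, AttentionMap]:
    """Functional wrapper: align `query_seq` against `context_seq`.

    Accepts (T, D) or (B, T, D) arrays; a fresh parameterization is drawn
    from `rng` unless an existing module is supplied.
    """
    q = np.asarray(query_seq, dtype=np.float32)
    c = np.asarray(context_seq, dtype=np.float32)
    squeeze = q.ndim == 2
    if squeeze:
        q, c = q[None], c[None]
    if module is None:
        module = CrossModalAttention(q.shape[-1], cfg,
                                     rng or np.random.default_rng(0))
    aligned, amap = module(Tensor(q), Tensor(c))
    out = aligned.data[0] if squeeze else aligned.data
    if squeeze:
        amap = AttentionMap(amap.weights[0], amap.direction)
    return out, amap


class MergeAligned(Module):
    """Rejoin attention output with the stream it refined."""

    def __init__(self, model_width: int, rng: np.random.Generator,
                 mode: str = "residual"):
        super().__init__()
        if mode not in ("residual", "concat_project"):
            raise ValueError(f"unknown merge mode {mode!r}")
        self.mode = mode
        if mode == "concat_project":
            self.proj = Linear(2 * model_width, model_width, rng)
        self.norm = LayerNorm(model_width)

    def forward(self, ctx: Tensor, aligned: Tensor) -> Tensor:
        if ctx.shape != aligned.shape:
            raise ValueError(f"merge shape mismatch: {ctx.shape} vs "
                             f"{aligned.shape}")
        if self.mode == "residual":
            return self.norm(ctx + aligned)
        return self.norm(self.proj(concat([ctx, aligned], axis=-1)))


def merge_aligned(ctx: np.ndarray, aligned: np.ndarray,
                  module: MergeAligned | None = None) -> np.ndarray:
    c = np.asarray(ctx, dtype=np.float32)
    a = np.asarray(aligned, dtype=np.float32)
    squeeze = c.ndim == 2
    if squeeze:
        c, a = c[None], a[None]
    if module is None:
        module = MergeAligned(c.shape[-1], np.random.default_rng(0))
    out = module(Tensor(c), Tensor(a)).data
    return out[0] if squeeze else out


class CoInteraction(Module):
    """Per-modality Bi-Mamba stacks with shared state-transition dynamics."""

    def __init__(self, cfg: BiMambaConfig, rng: np.random.Generator):
        super().__init__()
        self.stack_audio, self.stack_video = make_shared_stacks(cfg, rng)

    def forward(self, audio: Tensor, video: Tensor) -> tuple[Tensor, Tensor]:
        if audio.shape[-1] != video.shape[-1]:
            raise ValueError("co_interact requires equal model widths")
        return self.stack_audio(audio), self.stack_video(video)


def co_interact(audio: np.ndarray, video: np.ndarray,
                cfg: BiMambaConfig | None = None,
                module: CoInteraction | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Functional co-processing of two modality sequences ((T, D) or
    (B, T, D)); lengths may differ, widths must match."""
    a = np.asarray(audio, dtype=np.float32)
    v = np.asarray(video, dtype=np.float32)
    squeeze = a.ndim == 2
    if squeeze:
        a, v = a[None], v[None]
    if module is None:
        cfg = cfg or BiMambaConfig(model_width=a.shape[-1])
        module = CoInteraction(cfg, rng or np.random.default_rng(0))
    with_module = module(Tensor(a), Tensor(v))
    oa, ov = with_module[0].data, with_module[1].data
    return (oa[0], ov[0]) if squeeze else (oa, ov)


class Frontend(Module):
    """Per-time-step 1x1 convolution of raw features to the common width."""

    def __init__(self, in_features: int, out_width: int,
                 rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(in_features, out_width, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(x)


def frontend_project(x: ModalSequence | np.ndarray, out_width: int,
                     rng: np.random.Generator | None = None,
                     module: Frontend | None = None) -> np.ndarray:
    feats = x.features if isinstance(x, ModalSequence) else np.asarray(x)
    if module is None:
        module = Frontend(feats.shape[-1], out_width,
                          rng or np.random.default_rng(0))
    return module(Tensor(feats.astype(np.float32)[None])).data[0]


class CrossModalInteraction(Module):
    """Full interactive stage: front-ends, shared co-Mamba, bidirectional
    cross attention, residual merges.

    With ``use_attention=False`` the attention/merge stage is skipped
    (architecture ablation); the co-Mamba outputs pass through directly.
    """

    def __init__(self, f_audio: int, f_video: int, ssm_cfg: BiMambaConfig,
                 attn_cfg: AttentionConfig, rng: np.random.Generator,
                 use_attention: bool = True, merge: str = "residual"):
        super().__init__()
        d = ssm_cfg.model_width
        self.frontend_audio = Frontend(f_audio, d, rng)
        self.frontend_video = Frontend(f_video, d, rng)
        self.co = CoInteraction(ssm_cfg, rng)
        self.use_attention = use_attention
        if use_attention:
            a2v = AttentionConfig(attn_cfg.n_heads, attn_cfg.d_k, A2V)
            v2a = AttentionConfig(attn_cfg.n_heads, attn_cfg.d_k, V2A)
            self.attn_a2v = CrossModalAttention(d, a2v, rng)
            self.attn_v2a = CrossModalAttention(d, v2a, rng)
            self.merge_audio = MergeAligned(d, rng, mode=merge)
            self.merge_video = MergeAligned(d, rng, mode=merge)

    def forward(self, audio: Tensor, video: Tensor
                ) -> tuple[Tensor, Tensor, dict[str, AttentionMap]]:
        a = self.frontend_audio(audio)
        v = self.frontend_video(video)
        a, v = self.co(a, v)
        maps: dict[str, AttentionMap] = {}
        if self.use_attention:
            aligned_a, maps[A2V] = self.attn_a2v(a, v)
            aligned_v, maps[V2A] = self.attn_v2a(v, a)
            a = self.merge_audio(a, aligned_a)
            v = self.merge_video(v, aligned_v)
        return a, v, maps
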