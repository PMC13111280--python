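"""Multi-scale gated parallel fusion.

Two branches run in parallel on the interacted modality streams:

* a three-level temporal feature pyramid (lengths T, floor(T/2),
  floor(T/4)); at each level the two modalities are concatenated on
  channels and collapsed by a shared 1x1 convolution, the middle/top
  levels are upsampled to the bottom-level reference length, and the
  three level maps are concatenated on channels;
* a gated dynamic fusion unit whose sigmoid weights convexly combine the
  two streams per channel before a linear projection.

Both branch outputs share the same channel width, so ablating either one
halves the concatenated output width.  Disabling both is rejected at the
module level; the plain-concatenation baseline used by the architecture
ablation is a separate module (:class:`PlainConcatFusion`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm1d, Conv1d, DepthwiseConv1d, Dropout, Linear,
                 Module, Tensor, concat)
from .nn.ops import gather_time, maxpool1d, upsample_nearest

logger = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    model_width: int = 256
    level_width: int = 64          # 1x1-conv output channels per level (D_f)
    levels: int = 3
    kernel: int = 3
    dilation: int = 1
    dropout: float = 0.1
    upsample: str = "nearest"
    gate_granularity: str = "channel"   # or "timestep"
    use_fpn: bool = True
    use_gd: bool = True

    def __post_init__(self):
        if self.levels != 3:
            raise ValueError("the pyramid is defined with exactly 3 levels")
        if self.upsample not in ("nearest", "linear"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")
        if self.gate_granularity not in ("channel", "timestep"):
            raise ValueError(f"unknown gate granularity "
                             f"{self.gate_granularity!r}")

    @property
    def branch_width(self) -> int:
        return self.levels * self.level_width


@dataclass
class PyramidFeatures:
    """Three pyramid levels for one modality; higher levels may be None
    when the sequence is too short to pool."""

    level1: np.ndarray
    level2: np.ndarray | None
    level3: np.ndarray | None
    modality: str = ""

    def lengths(self) -> tuple[int, ...]:
        return tuple(lv.shape[-2] for lv in (self.level1, self.level2,
                                             self.level3) if lv is not None)


@dataclass
class FusedFeatures:
    features: np.ndarray
    provenance: str = "concatenated"   # fpn_path | gated_path | concatenated

    @property
    def n_steps(self) -> int:
        return self.features.shape[-2]


@dataclass
class GateOutput:
    """Sigmoid fusion weights and the gated single stream."""

    gamma: np.ndarray
    fused: np.ndarray            # after the output projection
    pre_projection: np.ndarray   # gamma * a + (1 - gamma) * v

    def __post_init__(self):
        g = np.asarray(self.gamma)
        if g.min() <= 0.0 or g.max() >= 1.0:
            raise ValueError("gate weights must lie strictly inside (0, 1)")


def _upsample(x: Tensor, target_len: int, mode: str) -> Tensor:
    if mode == "nearest":
        return upsample_nearest(x, target_len)
    # piecewise-linear between the two neighbouring source steps
    L = x.shape[1]
    pos = (np.arange(target_len) * L) / target_len
    lo_idx = np.floor(pos).astype(int)
    hi_idx = np.minimum(lo_idx + 1, L - 1)
    frac = Tensor((pos - lo_idx).astype(np.float32)[None, :, None])
    lo = gather_time(x, lo_idx)
    hi = gather_time(x, hi_idx)
    return lo * (1.0 - frac) + hi * frac


class PyramidNet(Module):
    """Per-modality temporal pyramid: conv/BN/dropout at level 1, then
    conv + max-pool(2, 2) twice."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.model_width
        self.cfg = cfg
        self.conv1 = DepthwiseConv1d(d, cfg.kernel, rng, padding="same",
                                     dilation=cfg.dilation)
        self.bn1 = BatchNorm1d(d)
        self.drop = Dropout(cfg.dropout, rng)
        self.conv2 = DepthwiseConv1d(d, cfg.kernel, rng, padding="same",
                                     dilation=cfg.dilation)
        self.conv3 = DepthwiseConv1d(d, cfg.kernel, rng, padding="same",
                                     dilation=cfg.dilation)

    def level1(self, x: Tensor) -> Tensor:
        return self.drop(self.bn1(self.conv1(x)))

    def downsample(self, x_prev: Tensor, conv: DepthwiseConv1d) -> Tensor | None:
        if x_prev.shape[1] < 2:
            logger.warning("pyramid level omitted: length %d cannot be "
                           "pooled by 2", x_prev.shape[1])
            return None
        return maxpool1d(conv(x_prev), window=2, stride=2)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor | None, Tensor | None]:
        l1 = self.level1(x)
        l2 = self.downsample(l1, self.conv2)
        l3 = self.downsample(l2, self.conv3) if l2 is not None else None
        return l1, l2, l3

    def flops(self, T: int) -> float:
        return (self.conv1.flops(T) + self.bn1.flops(T)
                + self.conv2.flops(T) + self.conv3.flops(T // 2))


class FpnFusion(Module):
    """Cross-modal pyramid fusion: per-level channel concat -> shared 1x1
    conv -> upsample to the bottom-level reference length -> concat levels."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.model_width
        self.pyr_audio = PyramidNet(cfg, rng)
        self.pyr_video = PyramidNet(cfg, rng)
        self.level_conv = Conv1d(2 * d, cfg.level_width, 1, rng)

    def forward(self, audio: Tensor, video: Tensor) -> Tensor:
        la = self.pyr_audio(audio)
        lv = self.pyr_video(video)
        t_ref = la[0].shape[1]
        parts = []
        for a_l, v_l in zip(la, lv):
            if a_l is None or v_l is None:
                parts.append(Tensor(np.zeros(
                    (audio.shape[0], t_ref, self.cfg.level_width),
                    dtype=np.float32)))
                continue
            z = self.level_conv(concat([a_l, v_l], axis=-1))
            if z.shape[1] != t_ref:
                z = _upsample(z, t_ref, self.cfg.upsample)
            parts.append(z)
        return concat(parts, axis=-1)

    def flops(self, T: int) -> float:
        per_level = sum(self.level_conv.flops(t)
                        for t in (T, T // 2, T // 4))
        return (self.pyr_audio.flops(T) + self.pyr_video.flops(T) + per_level)


class GatedFusion(Module):
    """gamma = sigmoid(W_g [a (+) v]); fused = gamma a + (1 - gamma) v,
    then a linear projection to the weighted multimodal stream."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.model_width
        self.cfg = cfg
        out = d if cfg.gate_granularity == "channel" else 1
        self.w_g = Linear(2 * d, out, rng)
        self.out_proj = Linear(d, cfg.branch_width, rng)

    def forward(self, audio: Tensor, video: Tensor
                ) -> tuple[Tensor, Tensor, Tensor]:
        if audio.shape[1] != video.shape[1]:
            raise ValueError(
                f"gated fusion requires equal temporal lengths, got "
                f"{audio.shape[1]} and {video.shape[1]}")
        z = concat([audio, video], axis=-1)
        if self.cfg.gate_granularity == "channel":
            gamma = self.w_g(z.mean(axis=1)).sigmoid()      # (B, D)
            gamma_b = gamma.expand_dims(1)                  # broadcast over T
        else:
            gamma = self.w_g(z).sigmoid()                   # (B, T, 1)
            gamma_b = gamma
        pre = gamma_b * audio + (1.0 - gamma_b) * video
        return self.out_proj(pre), gamma, pre

    def flops(self, T: int) -> float:
        d = self.cfg.model_width
        t_gate = 1 if self.cfg.gate_granularity == "channel" else T
        return (2.0 * t_gate * self.w_g.in_features * self.w_g.out_features
                + 3.0 * T * d + self.out_proj.flops(T))


class ParallelFusion(Module):
    """FPN branch and gated branch run in parallel and concatenated on
    channels at the reference temporal length."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        if not (cfg.use_fpn or cfg.use_gd):
            raise ValueError(
                "parallel fusion with both paths disabled is rejected; use "
                "PlainConcatFusion for the plain-concatenation baseline")
        self.cfg = cfg
        self.fpn = FpnFusion(cfg, rng) if cfg.use_fpn else None
        self.gated = GatedFusion(cfg, rng) if cfg.use_gd else None

    @property
    def out_width(self) -> int:
        return self.cfg.branch_width * ((self.fpn is not None)
                                        + (self.gated is not None))

    def forward(self, audio: Tensor, video: Tensor) -> Tensor:
        audio, video = align_lengths(audio, video, self.cfg.upsample)
        parts = []
        if self.fpn is not None:
            parts.append(self.fpn(audio, video))
        if self.gated is not None:
            parts.append(self.gated(audio, video)[0])
        return parts[0] if len(parts) == 1 else concat(parts, axis=-1)


class PlainConcatFusion(Module):
    """Ablation baseline: channel concatenation plus a 1x1 projection to
    the same output width as the dual-path module."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.proj = Linear(2 * cfg.model_width, 2 * cfg.branch_width, rng)

    @property
    def out_width(self) -> int:
        return 2 * self.cfg.branch_width

    def forward(self, audio: Tensor, video: Tensor) -> Tensor:
        audio, video = align_lengths(audio, video, self.cfg.upsample)
        return self.proj(concat([audio, video], axis=-1))


class UnimodalFusion(Module):
    """Single-modality stand-in for the dual-path module: pyramid levels
    (upsampled, concatenated, 1x1) alongside a direct projection, matching
    the dual-path output width."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.pyr = PyramidNet(cfg, rng)
        self.level_conv = Conv1d(cfg.model_width, cfg.level_width, 1, rng)
        self.direct = Linear(cfg.model_width, cfg.branch_width, rng)

    @property
    def out_width(self) -> int:
        return 2 * self.cfg.branch_width

    def forward(self, x: Tensor) -> Tensor:
        levels = self.pyr(x)
        t_ref = levels[0].shape[1]
        parts = []
        for lv in levels:
            if lv is None:
                parts.append(Tensor(np.zeros(
                    (x.shape[0], t_ref, self.cfg.level_width),
                    dtype=np.float32)))
                continue
            z = self.level_conv(lv)
            if z.shape[1] != t_ref:
                z = _upsample(z, t_ref, self.cfg.upsample)
            parts.append(z)
        parts.append(self.direct(x))
        return concat(parts, axis=-1)

    def flops(self, T: int) -> float:
        per_level = sum(self.level_conv.flops(t) for t in (T, T // 2, T // 4))
        return self.pyr.flops(T) + per_level + self.direct.flops(T)


def align_lengths(a: Tensor, b: Tensor, mode: str = "nearest"
                  ) -> tuple[Tensor, Tensor]:
    """Resample the longer stream to the shorter one's length."""
    ta, tb = a.shape[1], b.shape[1]
    if ta == tb:
        return a, b
    if ta > tb:
        return _upsample(a, tb, mode), b
    return a, _upsample(b, ta, mode)


# ---------------------------------------------------------------------------
# Functional wrappers (numpy in / numpy out) for the contract-level ops
# ---------------------------------------------------------------------------

def _as_batched(x: np.ndarray) -> tuple[Tensor, bool]:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        return Tensor(x[None]), True
    return Tensor(x), False


def fpn_level1(x: np.ndarray, cfg: FusionConfig | None = None,
               module: PyramidNet | None = None,
               training: bool = False) -> np.ndarray:
    """Level-1 transform: conv(k=3, stride 1, same) -> BN -> dropout."""
    xt, squeeze = _as_batched(x)
    if module is None:
        cfg = cfg or FusionConfig(model_width=xt.shape[-1])
        module = PyramidNet(cfg, np.random.default_rng(0))
    module.train() if training else module.eval()
    out = module.level1(xt).data
    return out[0] if squeeze else out


def fpn_downsample(x_prev: np.ndarray, cfg: FusionConfig | None = None,
                   module: PyramidNet | None = None) -> np.ndarray | None:
    """conv(k=3) then max-pool(2, 2): length L -> floor(L / 2).

    Returns None (with a logged warning) for L == 1.
    """
    xt, squeeze = _as_batched(x_prev)
    if module is None:
        cfg = cfg or FusionConfig(model_width=xt.shape[-1])
        module = PyramidNet(cfg, np.random.default_rng(0))
    module.eval()
    out = module.downsample(xt, module.conv2)
    if out is None:
        return None
    return out.data[0] if squeeze else out.data


def build_pyramid(x: np.ndarray, modality: str = "",
                  cfg: FusionConfig | None = None,
                  module: PyramidNet | None = None) -> PyramidFeatures:
    xt, squeeze = _as_batched(x)
    if module is None:
        cfg = cfg or FusionConfig(model_width=xt.shape[-1])
        module = PyramidNet(cfg, np.random.default_rng(0))
    module.eval()
    l1, l2, l3 = module(xt)

    def unwrap(t):
        if t is None:
            return None
        return t.data[0] if squeeze else t.data

    return PyramidFeatures(unwrap(l1), unwrap(l2), unwrap(l3), modality)


def fpn_fuse(pyr_audio: PyramidFeatures, pyr_video: PyramidFeatures,
             cfg: FusionConfig | None = None,
             module: Conv1d | None = None,
             upsample: str = "nearest") -> FusedFeatures:
    """Fuse two pyramids: per-level channel concat, shared 1x1 conv to D_f,
    upsample to the bottom-level reference length, concat the levels."""
    la = (pyr_audio.level1, pyr_audio.level2, pyr_audio.level3)
    lv = (pyr_video.level1, pyr_video.level2, pyr_video.level3)
    if la[0].shape[-1] != lv[0].shape[-1]:
        raise ValueError("pyramids disagree on channel width")
    squeeze = la[0].ndim == 2
    t_ref = la[0].shape[-2]
    d = la[0].shape[-1]
    batch = 1 if squeeze else la[0].shape[0]
    if module is None:
        cfg = cfg or FusionConfig(model_width=d)
        module = Conv1d(2 * d, cfg.level_width, 1, np.random.default_rng(0))
    width = module.out_channels
    parts = []
    for a_l, v_l in zip(la, lv):
        if a_l is None or v_l is None:
            parts.append(Tensor(np.zeros((batch, t_ref, width),
                                         dtype=np.float32)))
            continue
        at, _ = _as_batched(a_l)
        vt, _ = _as_batched(v_l)
        z = module(concat([at, vt], axis=-1))
        if z.shape[1] != t_ref:
            z = _upsample(z, t_ref, upsample)
        parts.append(z)
    out = concat(parts, axis=-1).data
    return FusedFeatures(out[0] if squeeze else out, provenance="fpn_path")


def gated_fusion(audio_feat: np.ndarray, video_feat: np.ndarray,
                 cfg: FusionConfig | None = None,
                 module: GatedFusion | None = None) -> GateOutput:
    at, squeeze = _as_batched(audio_feat)
    vt, _ = _as_batched(video_feat)
    if module is None:
        cfg = cfg or FusionConfig(model_width=at.shape[-1])
        module = GatedFusion(cfg, np.random.default_rng(0))
    module.eval()
    fused, gamma, pre = module(at, vt)
    if squeeze:
        return GateOutput(gamma.data[0], fused.data[0], pre.data[0])
    return GateOutput(gamma.data, fused.data, pre.data)


def parallel_fuse(ctx_audio: np.ndarray, ctx_video: np.ndarray,
                  cfg: FusionConfig | None = None,
                  module: ParallelFusion | None = None) -> FusedFeatures:
    at, squeeze = _as_batched(ctx_audio)
    vt, _ = _as_batched(ctx_video)
    if module is None:
        cfg = cfg or FusionConfig(model_width=at.shape[-1])
        module = ParallelFusion(cfg, np.random.default_rng(0))
    module.eval()
    out = module(at, vt).data
    return FusedFeatures(out[0] if squeeze else out, provenance="concatenated")
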