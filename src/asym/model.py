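"""End-to-end model: interaction stage -> parallel fusion -> enhancement
head, with every architecture-ablation switch exposed."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import (FusionConfig, ParallelFusion, PlainConcatFusion,
                     UnimodalFusion)
from .head import EnhanceHead
from .interaction import (AttentionConfig, AttentionMap,
                          CrossModalInteraction, Frontend)
from .nn import Module, Tensor
from .ssm_core import BiMambaConfig, BiMambaStack


@dataclass
class ModelConfig:
    """All architecture hyperparameters and ablation switches.

    ``n_blocks`` counts Bi-Mamba blocks per stage: the interaction stage
    holds one block stack per modality of depth ``n_blocks // 2`` (so the
    default 2 gives one audio + one video block), the enhancement stage a
    single stack of depth ``n_blocks``.
    """

    model_width: int = 256
    state_dim: int = 16
    conv_kernel: int = 4
    expansion: float = 0.5
    n_blocks: int = 2
    static_ssm: bool = False
    # cross-modal attention
    n_heads: int = 2
    d_k: int = 16
    merge: str = "residual"
    # fusion
    level_width: int = 64
    fpn_kernel: int = 3
    fpn_dilation: int = 1
    dropout: float = 0.1
    upsample: str = "nearest"
    gate_granularity: str = "channel"
    # head
    head_width: int = 128
    head_state_dim: int = 16
    n_res_blocks: int = 1
    res_kernel: int = 3
    pool: str = "mean"
    # ablation switches
    audio_only: bool = False
    video_only: bool = False
    no_cma: bool = False
    uni_mamba: bool = False
    no_fpn: bool = False
    no_gd: bool = False
    no_enhance: bool = False

    def __post_init__(self):
        if self.audio_only and self.video_only:
            raise ValueError("audio_only and video_only are contradictory")

    @property
    def unimodal(self) -> bool:
        return self.audio_only or self.video_only

    def interaction_depth(self) -> int:
        return max(1, self.n_blocks // 2)

    def ssm_config(self) -> BiMambaConfig:
        return BiMambaConfig(model_width=self.model_width,
                             state_dim=self.state_dim,
                             conv_kernel=self.conv_kernel,
                             expansion=self.expansion,
                             n_blocks=self.interaction_depth(),
                             static_ssm=self.static_ssm,
                             bidirectional=not self.uni_mamba)

    def head_ssm_config(self) -> BiMambaConfig:
        return BiMambaConfig(model_width=self.head_width,
                             state_dim=self.head_state_dim,
                             conv_kernel=self.conv_kernel,
                             expansion=self.expansion,
                             n_blocks=self.n_blocks,
                             static_ssm=self.static_ssm,
                             bidirectional=not self.uni_mamba)

    def fusion_config(self) -> FusionConfig:
        return FusionConfig(model_width=self.model_width,
                            level_width=self.level_width,
                            kernel=self.fpn_kernel,
                            dilation=self.fpn_dilation,
                            dropout=self.dropout,
                            upsample=self.upsample,
                            gate_granularity=self.gate_granularity,
                            use_fpn=not self.no_fpn,
                            use_gd=not self.no_gd)


class AsymModel(Module):
    """Dual-stream (or ablated single-stream) sequence classifier."""

    def __init__(self, cfg: ModelConfig, f_audio: int, f_video: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        fus_cfg = cfg.fusion_config()
        if cfg.unimodal:
            f_in = f_audio if cfg.audio_only else f_video
            self.frontend = Frontend(f_in, cfg.model_width, rng)
            self.stack = BiMambaStack(cfg.ssm_config(), rng)
            self.fusion = UnimodalFusion(fus_cfg, rng)
        else:
            self.interaction = CrossModalInteraction(
                f_audio, f_video, cfg.ssm_config(),
                AttentionConfig(cfg.n_heads, cfg.d_k), rng,
                use_attention=not cfg.no_cma, merge=cfg.merge)
            if cfg.no_fpn and cfg.no_gd:
                self.fusion = PlainConcatFusion(fus_cfg, rng)
            else:
                self.fusion = ParallelFusion(fus_cfg, rng)
        self.head = EnhanceHead(self.fusion.out_width, cfg.head_ssm_config(),
                                rng, n_res_blocks=cfg.n_res_blocks,
                                res_kernel=cfg.res_kernel, pool=cfg.pool,
                                use_enhance=not cfg.no_enhance)
        self.last_attention: dict[str, AttentionMap] = {}

    def forward(self, audio: Tensor | None, video: Tensor | None) -> Tensor:
        """Return raw logits (B,). Unimodal configs ignore the absent stream."""
        if self.cfg.unimodal:
            x = audio if self.cfg.audio_only else video
            if x is None:
                raise ValueError("configured modality missing from the input")
            z = self.stack(self.frontend(x))
            fused = self.fusion(z)
        else:
            if audio is None or video is None:
                raise ValueError("both modalities are required")
            a, v, maps = self.interaction(audio, video)
            self.last_attention = maps
            fused = self.fusion(a, v)
        return self.head(fused)

    def predict_logits(self, audio: np.ndarray | None,
                       video: np.ndarray | None) -> np.ndarray:
        from .nn import no_grad
        with no_grad():
            self.eval()
            ta = Tensor(np.asarray(audio, dtype=np.float32)) \
                if audio is not None else None
            tv = Tensor(np.asarray(video, dtype=np.float32)) \
                if video is not None else None
            return self.forward(ta, tv).data.copy()

    def flops(self, T: int) -> float:
        total = self.head.flops(T)
        if self.cfg.unimodal:
            total += self.frontend.flops(T) + self.stack.flops(T)
            total += self.fusion.flops(T)
        else:
            total += self.interaction.flops(T) + self.fusion.flops(T)
        return total


def build_model(cfg: ModelConfig, f_audio: int, f_video: int,
                seed: int = 0) -> AsymModel:
    return AsymModel(cfg, f_audio, f_video, np.random.default_rng(seed))
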