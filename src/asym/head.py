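"""Enhancement head: residual conv blocks plus Bi-Mamba refinement of the
fused single stream, temporal pooling and a linear sigmoid classifier."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm1d, Conv1d, Linear, Module, Tensor
from .ssm_core import BiMambaConfig, BiMambaStack


@dataclass
class ResBlockConfig:
    channels: int = 128
    kernel: int = 3
    n_convs: int = 2

    def __post_init__(self):
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd for same-padding")
        if self.n_convs != 2:
            raise ValueError("the residual block stacks exactly two convolutions")


@dataclass
class ClassifierOutput:
    logit: np.ndarray
    probability: np.ndarray
    predicted_label: np.ndarray

    def __post_init__(self):
        self.logit = np.atleast_1d(np.asarray(self.logit, dtype=np.float64))
        self.probability = np.atleast_1d(np.asarray(self.probability,
                                                    dtype=np.float64))
        self.predicted_label = np.atleast_1d(np.asarray(self.predicted_label,
                                                        dtype=np.int64))


class ResBlock(Module):
    """conv -> BN -> ReLU -> conv -> BN, identity skip, final ReLU."""

    def __init__(self, cfg: ResBlockConfig, rng: np.random.Generator):
        super().__init__()
        c, k = cfg.channels, cfg.kernel
        self.conv1 = Conv1d(c, c, k, rng, padding="same")
        self.bn1 = BatchNorm1d(c)
        self.conv2 = Conv1d(c, c, k, rng, padding="same")
        self.bn2 = BatchNorm1d(c)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (x + y).relu()


class EnhanceHead(Module):
    """Residual stack then Bi-Mamba block(s) on the fused stream, followed
    by temporal pooling and the linear classifier.

    ``use_enhance=False`` turns the refinement into an identity
    pass-through so the classifier consumes the fused features directly.
    """

    def __init__(self, in_width: int, ssm_cfg: BiMambaConfig,
                 rng: np.random.Generator, n_res_blocks: int = 1,
                 res_kernel: int = 3, pool: str = "mean",
                 use_enhance: bool = True):
        super().__init__()
        if pool not in ("mean", "max", "last"):
            raise ValueError(f"unknown pooling {pool!r}")
        self.pool = pool
        self.use_enhance = use_enhance
        d = ssm_cfg.model_width
        if use_enhance:
            self.in_proj = Linear(in_width, d, rng)
            self.res_blocks = [
                ResBlock(ResBlockConfig(channels=d, kernel=res_kernel), rng)
                for _ in range(n_res_blocks)
            ]
            self.mamba = BiMambaStack(ssm_cfg, rng)
            clf_width = d
        else:
            clf_width = in_width
        self.classifier = Linear(clf_width, 1, rng)

    def enhance(self, fused: Tensor) -> Tensor:
        if not self.use_enhance:
            return fused
        x = self.in_proj(fused)
        for rb in self.res_blocks:
            x = rb(x)
        return self.mamba(x)

    def pooled(self, x: Tensor) -> Tensor:
        if self.pool == "mean":
            return x.mean(axis=1)
        if self.pool == "max":
            return x.max(axis=1)
        return x[:, -1, :]

    def forward(self, fused: Tensor) -> Tensor:
        """Return raw logits, shape (B,)."""
        x = self.enhance(fused)
        return self.classifier(self.pooled(x)).reshape(-1)

    def flops(self, T: int) -> float:
        total = self.classifier.flops(1)  # applied once after pooling
        if self.use_enhance:
            total += self.in_proj.flops(T) + self.mamba.flops(T)
            total += sum(rb.flops(T) for rb in self.res_blocks)
        return total


def classify_logits(logits: np.ndarray, threshold: float = 0.5
                    ) -> ClassifierOutput:
    """Sigmoid + thresholding with the >= convention (ties to positive)."""
    z = np.atleast_1d(np.asarray(logits, dtype=np.float64))
    prob = 1.0 / (1.0 + np.exp(-z))
    return ClassifierOutput(z, prob, (prob >= threshold).astype(np.int64))


# -- functional wrappers -----------------------------------------------------

def res_block(x: np.ndarray, module: ResBlock | None = None,
              rng: np.random.Generator | None = None,
              training: bool = False) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    if module is None:
        module = ResBlock(ResBlockConfig(channels=arr.shape[-1]),
                          rng or np.random.default_rng(0))
    module.train() if training else module.eval()
    out = module(Tensor(arr)).data
    return out[0] if squeeze else out


def enhance(fused: np.ndarray, module: EnhanceHead | None = None,
            rng: np.random.Generator | None = None) -> np.ndarray:
    arr = np.asarray(fused, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    if module is None:
        cfg = BiMambaConfig(model_width=arr.shape[-1], state_dim=4, n_blocks=1)
        module = EnhanceHead(arr.shape[-1], cfg,
                             rng or np.random.default_rng(0))
    module.eval()
    out = module.enhance(Tensor(arr)).data
    return out[0] if squeeze else out


def classify(enhanced: np.ndarray, module: EnhanceHead | None = None,
             weights: np.ndarray | None = None,
             bias: float = 0.0) -> ClassifierOutput:
    """Temporal mean pooling -> linear map -> sigmoid, threshold 0.5.

    Either an EnhanceHead (whose classifier is used on the already
    enhanced sequence) or explicit (weights, bias) may be supplied.
    """
    arr = np.asarray(enhanced, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    pooled = arr.mean(axis=1)
    if module is not None:
        w = module.classifier.weight.data.astype(np.float64)
        b = float(module.classifier.bias.data[0])
    else:
        w = (np.zeros((arr.shape[-1], 1)) if weights is None
             else np.asarray(weights, dtype=np.float64).reshape(-1, 1))
        b = float(bias)
    logit = pooled @ w + b
    out = classify_logits(logit.ravel())
    if squeeze:
        return ClassifierOutput(out.logit[0], out.probability[0],
                                out.predicted_label[0])
    return out
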