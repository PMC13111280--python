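"""Selective state-space scan and the bidirectional Mamba block.

Two SSM parameterizations are provided:

* static — constant diagonal transition ``A_bar``, input map ``B_bar`` and
  output map ``C`` applied through the literal recursions
  ``h_t = A_bar * h_{t-1} + B_bar * x_t`` / ``y_t = C * h_t`` (forward) and
  the mirrored tail-to-head recursion (backward).  This is the exactly
  testable mode (``static_ssm=True``).
* selective (default) — input-dependent discretisation step and input/output
  maps with a log-spaced diagonal state matrix and zero-order-hold
  discretisation, following the standard selective-SSM recipe.

The state-transition parameterization (the diagonal of A plus, in selective
mode, its discretisation projection) can be *shared* between two blocks via
:func:`make_shared_pair`; input/output maps stay block-private.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import (DepthwiseConv1d, LayerNorm, Linear, Module, Parameter,
                 Tensor, concat)
from .nn.layers import _kaiming_uniform
from .nn.ops import linear_recurrence

FORWARD = "forward"
BACKWARD = "backward"


# ---------------------------------------------------------------------------
# Literal scan (plain numpy, float64) — the contract-level operation
# ---------------------------------------------------------------------------

@dataclass
class SSMParams:
    """Constant discretised SSM parameters for one direction.

    A_bar : (N,) or (D, N) diagonal state transition
    B_bar : (D, N) per-channel input map
    C     : (D, N) per-channel output map
    """

    A_bar: np.ndarray
    B_bar: np.ndarray
    C: np.ndarray
    direction: str = FORWARD

    def __post_init__(self):
        self.A_bar = np.asarray(self.A_bar, dtype=np.float64)
        self.B_bar = np.asarray(self.B_bar, dtype=np.float64)
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.direction not in (FORWARD, BACKWARD):
            raise ValueError(f"direction must be forward/backward, got {self.direction!r}")
        n_state = self.B_bar.shape[-1]
        if n_state < 1:
            raise ValueError("state dimension must be >= 1")
        if self.A_bar.shape[-1] != n_state or self.C.shape[-1] != n_state:
            raise ValueError("A_bar, B_bar, C disagree on state dimension")


def _check_finite(x: np.ndarray, what: str = "input"):
    bad = ~np.isfinite(x)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"non-finite {what}: first offending entry at time index {idx[0]}, "
            f"position {idx}")


def ssm_scan(params: SSMParams, x: np.ndarray) -> np.ndarray:
    """Run the diagonal SSM recursion over a (T, D) sequence.

    Forward direction: ``h_t = A_bar h_{t-1} + B_bar x_t``, ``y_t = C h_t``
    with ``h_0 = 0``.  Backward direction runs the mirrored recursion
    ``h_i = A_bar h_{i+1} + B_bar x_i`` from the tail, which equals
    ``reverse(forward_scan(reverse(x)))``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    _check_finite(x)
    if params.direction == BACKWARD:
        return ssm_scan(
            SSMParams(params.A_bar, params.B_bar, params.C, FORWARD),
            x[::-1])[::-1]
    T, D = x.shape
    A = np.broadcast_to(params.A_bar, params.B_bar.shape)  # (D, N)
    h = np.zeros_like(params.B_bar)
    y = np.empty((T, D), dtype=np.float64)
    for t in range(T):
        h = A * h + params.B_bar * x[t][:, None]
        y[t] = (params.C * h).sum(axis=-1)
    return y


# ---------------------------------------------------------------------------
# Trainable blocks
# ---------------------------------------------------------------------------

@dataclass
class BiMambaConfig:
    """Widths and switches for one Bi-Mamba block / stack."""

    model_width: int = 256
    state_dim: int = 16
    conv_kernel: int = 4
    expansion: float = 0.5
    n_blocks: int = 2
    static_ssm: bool = False
    bidirectional: bool = True
    dt_rank: int | None = None
    share_group: str | None = None

    def __post_init__(self):
        if self.model_width <= 0:
            raise ValueError("model_width must be > 0")
        if self.state_dim <= 0:
            raise ValueError("state_dim must be > 0")
        if self.conv_kernel < 1:
            raise ValueError("conv_kernel must be >= 1")

    @property
    def inner_width(self) -> int:
        return max(1, int(round(self.model_width * self.expansion)))

    def resolved_dt_rank(self) -> int:
        if self.dt_rank is not None:
            return self.dt_rank
        return max(1, self.inner_width // 16)


@dataclass
class ScanState:
    """Hidden state snapshot (mainly for introspection/testing)."""

    h: np.ndarray
    t: int = 0

    def __post_init__(self):
        if not np.isfinite(self.h).all():
            raise ValueError("non-finite hidden state")


class TransitionParams(Module):
    """The shareable state-transition parameterization for one direction."""

    def __init__(self, cfg: BiMambaConfig, rng: np.random.Generator):
        super().__init__()
        d_in, n = cfg.inner_width, cfg.state_dim
        self.static = cfg.static_ssm
        if self.static:
            # |A_bar| < 1 keeps the literal recursion stable
            self.A_bar = Parameter(rng.uniform(0.3, 0.95, size=(d_in, n)))
        else:
            # log-spaced diagonal (S4D-real style), A = -exp(A_log)
            a = np.tile(np.arange(1, n + 1, dtype=np.float32), (d_in, 1))
            self.A_log = Parameter(np.log(a))
            r = cfg.resolved_dt_rank()
            self.dt_down = Parameter(_kaiming_uniform(rng, (d_in, r), d_in))
            self.dt_up = Parameter(_kaiming_uniform(rng, (r, d_in), r))
            dt_init = np.exp(rng.uniform(math.log(1e-3), math.log(1e-1),
                                         size=d_in))
            # softplus^-1 so that softplus(dt_bias) == dt_init
            self.dt_bias = Parameter(np.log(np.expm1(dt_init)))


class SSMStream(Module):
    """conv -> SiLU -> directional SSM; one direction of a Bi-Mamba block."""

    def __init__(self, cfg: BiMambaConfig, direction: str,
                 rng: np.random.Generator,
                 transition: TransitionParams | None = None):
        super().__init__()
        if direction not in (FORWARD, BACKWARD):
            raise ValueError(f"bad direction {direction!r}")
        self.direction = direction
        self.cfg = cfg
        d_in, n = cfg.inner_width, cfg.state_dim
        self.conv = DepthwiseConv1d(d_in, cfg.conv_kernel, rng, padding="causal")
        self.transition = transition if transition is not None \
            else TransitionParams(cfg, rng)
        if cfg.static_ssm:
            self.B_bar = Parameter(_kaiming_uniform(rng, (d_in, n), n))
            self.C = Parameter(_kaiming_uniform(rng, (d_in, n), n))
        else:
            self.W_B = Parameter(_kaiming_uniform(rng, (d_in, n), d_in))
            self.W_C = Parameter(_kaiming_uniform(rng, (d_in, n), d_in))
            self.D_skip = Parameter(np.ones(d_in))

    def forward(self, u: Tensor) -> Tensor:
        if self.direction == BACKWARD:
            u = u.flip(1)
        w = self.conv(u).silu()
        if self.cfg.static_ssm:
            y = self._scan_static(w)
        else:
            y = self._scan_selective(w)
        if self.direction == BACKWARD:
            y = y.flip(1)
        return y

    def _scan_static(self, w: Tensor) -> Tensor:
        B, T, _ = w.shape
        ones = Tensor(np.ones((B, T, 1, 1), dtype=np.float32))
        a = ones * self.transition.A_bar
        binc = self.B_bar * w.expand_dims(-1)
        h = linear_recurrence(a, binc)
        return (h * self.C).sum(axis=-1)

    def _scan_selective(self, w: Tensor) -> Tensor:
        tr = self.transition
        dt = ((w @ tr.dt_down) @ tr.dt_up + tr.dt_bias).softplus()  # (B,T,Din)
        A = -(tr.A_log.exp())                                       # (Din,N)
        a = (dt.expand_dims(-1) * A).exp()                          # ZOH decay
        Bt = (w @ self.W_B).expand_dims(2)                          # (B,T,1,N)
        binc = dt.expand_dims(-1) * Bt * w.expand_dims(-1)
        h = linear_recurrence(a, binc)
        Ct = (w @ self.W_C).expand_dims(2)
        return (h * Ct).sum(axis=-1) + self.D_skip * w

    def flops(self, T: int) -> float:
        d_in, n = self.cfg.inner_width, self.cfg.state_dim
        total = self.conv.flops(T)
        if self.cfg.static_ssm:
            total += T * d_in * n * 8.0
        else:
            r = self.cfg.resolved_dt_rank()
            total += 4.0 * T * d_in * r            # dt projection
            total += 4.0 * T * d_in * n            # B and C projections
            total += T * d_in * n * 10.0           # discretise + recur + emit
            total += 2.0 * T * d_in                # skip path
        return total


class BiMambaBlock(Module):
    """Bidirectional Mamba block: linear in, twin conv/SiLU/SSM streams
    (the backward one over the time-reversed sequence, flipped back),
    concatenation, linear out, layer norm."""

    def __init__(self, cfg: BiMambaConfig, rng: np.random.Generator,
                 shared: dict[str, TransitionParams] | None = None):
        super().__init__()
        self.cfg = cfg
        d, d_in = cfg.model_width, cfg.inner_width
        self.in_proj = Linear(d, d_in, rng)
        shared = shared or {}
        self.fwd = SSMStream(cfg, FORWARD, rng, transition=shared.get(FORWARD))
        self.bwd = SSMStream(cfg, BACKWARD, rng,
                             transition=shared.get(BACKWARD)) \
            if cfg.bidirectional else None
        n_streams = 2 if cfg.bidirectional else 1
        self.out_proj = Linear(n_streams * d_in, d, rng)
        self.norm = LayerNorm(d)

    def transitions(self) -> dict[str, TransitionParams]:
        out = {FORWARD: self.fwd.transition}
        if self.bwd is not None:
            out[BACKWARD] = self.bwd.transition
        return out

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.cfg.model_width:
            raise ValueError(
                f"input width {x.shape[-1]} != configured model_width "
                f"{self.cfg.model_width}")
        u = self.in_proj(x)
        yf = self.fwd(u)
        if self.bwd is not None:
            y = concat([yf, self.bwd(u)], axis=-1)
        else:
            y = yf
        return self.norm(self.out_proj(y))


class BiMambaStack(Module):
    """n_blocks Bi-Mamba blocks applied in sequence, with residual adds."""

    def __init__(self, cfg: BiMambaConfig, rng: np.random.Generator,
                 shared: list[dict[str, TransitionParams]] | None = None):
        super().__init__()
        self.blocks = [
            BiMambaBlock(cfg, rng, shared=shared[i] if shared else None)
            for i in range(cfg.n_blocks)
        ]

    def transitions(self) -> list[dict[str, TransitionParams]]:
        return [b.transitions() for b in self.blocks]

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = x + b(x)
        return x


def make_shared_pair(cfg: BiMambaConfig, rng: np.random.Generator
                     ) -> tuple[BiMambaBlock, BiMambaBlock]:
    """Two blocks whose state-transition parameterizations are one object.

    Perturbing the shared transition through either block affects both;
    all other parameters (conv, input/output maps, projections) are private.
    """
    block_a = BiMambaBlock(cfg, rng)
    block_b = BiMambaBlock(cfg, rng, shared=block_a.transitions())
    return block_a, block_b


def make_shared_stacks(cfg: BiMambaConfig, rng: np.random.Generator
                       ) -> tuple[BiMambaStack, BiMambaStack]:
    stack_a = BiMambaStack(cfg, rng)
    stack_b = BiMambaStack(cfg, rng, shared=stack_a.transitions())
    return stack_a, stack_b
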