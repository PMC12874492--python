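"""Feature-Gating (FG) attention gate for skip connections.

The gate fuses a high-resolution encoder feature x^l with a coarser,
semantically richer decoder gating signal g.  Both are linearly mapped
(1×1 convolutions) to a shared intermediate width, added, passed through
ReLU, compressed to one channel by ψ, and squashed by a sigmoid into a
per-pixel coefficient α ∈ (0, 1) that reweights x^l:

    α = σ2(ψᵀ σ1(Wxᵀ x^l + bx + Wgᵀ g_up + bg) + bψ),    x̂^l = x^l ⊙ α

g is bilinearly upsampled to x^l's spatial size first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Module, Parameter, Tensor
from .errors import InvalidParameterError, NumericError
from .mpv import _init_w

__all__ = ["FGParams", "FGGate", "attention_gate", "upsample_gate"]


@dataclass
class FGParams:
    """Weights of the gate: W_x (C_l, C_int), W_g (C_g, C_int), psi (C_int,)."""

    W_x: np.ndarray
    b_x: np.ndarray
    W_g: np.ndarray
    b_g: np.ndarray
    psi: np.ndarray
    b_psi: float

    def __post_init__(self):
        self.W_x = np.asarray(self.W_x, dtype=np.float64)
        self.W_g = np.asarray(self.W_g, dtype=np.float64)
        self.b_x = np.asarray(self.b_x, dtype=np.float64)
        self.b_g = np.asarray(self.b_g, dtype=np.float64)
        self.psi = np.asarray(self.psi, dtype=np.float64).reshape(-1)
        self.b_psi = float(self.b_psi)
        c_int = self.W_x.shape[1]
        if c_int < 1:
            raise InvalidParameterError("intermediate width must be >= 1")
        if self.W_g.shape[1] != c_int or self.psi.shape[0] != c_int:
            raise InvalidParameterError("W_x, W_g and psi disagree on C_int")


class FGGate(Module):
    """Trainable attention gate on channels-last feature maps."""

    def __init__(self, c_skip: int, c_gate: int, c_int: int | None = None,
                 upsample: str = "bilinear",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        c_int = c_int or max(1, c_skip // 2)
        if upsample not in ("bilinear", "nearest"):
            raise InvalidParameterError(f"unknown upsample mode {upsample!r}")
        self.c_skip, self.c_gate, self.c_int = c_skip, c_gate, c_int
        self.upsample = upsample
        self.w_x = Parameter(_init_w(rng, c_skip, c_int))
        self.b_x = Parameter(np.zeros(c_int))
        self.w_g = Parameter(_init_w(rng, c_gate, c_int))
        self.b_g = Parameter(np.zeros(c_int))
        self.psi = Parameter(_init_w(rng, c_int, 1))
        self.b_psi = Parameter(np.zeros(1))

    @classmethod
    def from_params(cls, params: FGParams, upsample: str = "bilinear") -> "FGGate":
        gate = cls(params.W_x.shape[0], params.W_g.shape[0],
                   params.W_x.shape[1], upsample=upsample)
        gate.w_x.data = params.W_x.copy()
        gate.b_x.data = params.b_x.astype(np.float64).copy()
        gate.w_g.data = params.W_g.copy()
        gate.b_g.data = params.b_g.astype(np.float64).copy()
        gate.psi.data = params.psi.reshape(-1, 1).copy()
        gate.b_psi.data = np.array([params.b_psi])
        return gate

    def __call__(self, x_skip: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (gated skip feature, α map of shape (B, H, W, 1))."""
        B, H, W, C = x_skip.shape
        if C != self.c_skip or g.shape[-1] != self.c_gate:
            raise InvalidParameterError(
                f"gate built for (skip={self.c_skip}, gate={self.c_gate}) channels, "
                f"got ({C}, {g.shape[-1]})")
        if g.shape[1] != H or g.shape[2] != W:
            if g.shape[1] > H or g.shape[2] > W:
                raise InvalidParameterError("gating signal larger than skip feature")
            up = T.bilinear_upsample if self.upsample == "bilinear" else T.nearest_upsample
            g = up(g, H, W)
        xp = T.linear(x_skip, self.w_x, self.b_x)
        gp = T.linear(g, self.w_g, self.b_g)
        act = T.linear(T.relu(T.add(xp, gp)), self.psi, self.b_psi)
        alpha = T.sigmoid(act)                       # (B, H, W, 1)
        return T.mul(x_skip, alpha), alpha


def upsample_gate(g: np.ndarray, target_h: int, target_w: int,
                  mode: str = "bilinear") -> np.ndarray:
    """Upsample a (C, H', W') gating signal to (C, H, W).

    Bilinear with half-pixel centres by default; ``mode="nearest"``
    available.  Downsampling requests are rejected.
    """
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 3:
        raise InvalidParameterError("gating signal must have shape (C, H, W)")
    C, H, W = g.shape
    if target_h < H or target_w < W:
        raise InvalidParameterError("upsample_gate cannot downsample")
    if (H, W) == (target_h, target_w):
        return g
    t = Tensor(np.ascontiguousarray(g.transpose(1, 2, 0))[None])
    up = T.bilinear_upsample if mode == "bilinear" else T.nearest_upsample
    return up(t, target_h, target_w).data[0].transpose(2, 0, 1)


def attention_gate(x_l: np.ndarray, g: np.ndarray, params: FGParams,
                   upsample: str = "bilinear") -> tuple[np.ndarray, np.ndarray]:
    """Apply the gate to a single (C_l, H, W) skip feature.

    Returns (gated feature (C_l, H, W), α (1, H, W)); α is strictly inside
    (0, 1) for finite inputs.
    """
    x_l = np.asarray(x_l, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if not (np.isfinite(x_l).all() and np.isfinite(g).all()):
        raise NumericError("attention_gate requires finite inputs")
    if x_l.ndim != 3 or g.ndim != 3:
        raise InvalidParameterError("x_l and g must have shape (C, H, W)")
    if x_l.shape[0] != params.W_x.shape[0] or g.shape[0] != params.W_g.shape[0]:
        raise InvalidParameterError("channel counts do not match gate weights")
    gate = FGGate.from_params(params, upsample=upsample)
    xt = Tensor(np.ascontiguousarray(x_l.transpose(1, 2, 0))[None])
    gt = Tensor(np.ascontiguousarray(g.transpose(1, 2, 0))[None])
    gated, alpha = gate(xt, gt)
    return (gated.data[0].transpose(2, 0, 1),
            alpha.data[0].transpose(2, 0, 1))
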