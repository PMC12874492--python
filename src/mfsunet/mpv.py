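"""Multi-Path Vision Mamba (MPV) block.

A feature map is layer-normalised, flattened along four directional scan
paths (row/column raster order, each forward and backward), each 1-D
sequence is run through an independent gated Mamba branch, restored to the
2-D grid and combined with a learnable per-channel residual scale β.  The
four branch outputs are concatenated channel-wise, normalised again and
projected back to the input width, so the block preserves (H, W, C).
"""

from __future__ import annotations

import numpy as np

from . import _tensor as T
from ._tensor import Module, Parameter, Tensor
from .errors import InvalidParameterError
from .ssm import fused_ssm_scan_op, ssm_scan_op

__all__ = [
    "SCAN_PATHS", "directional_flatten", "directional_unflatten",
    "MambaBranch", "MPVBlock", "mpv_forward",
]

SCAN_PATHS = ("row_forward", "row_backward", "col_forward", "col_backward")


# ---------------------------------------------------------------------------
# scan-path bijections
# ---------------------------------------------------------------------------

def _flatten_t(x: Tensor, path: str) -> Tensor:
    """Tensor flatten: (B, H, W, C) -> (B, H*W, C) in scan order."""
    B, H, W, C = x.shape
    if path == "row_forward":
        return T.reshape(x, (B, H * W, C))
    if path == "row_backward":
        return T.flip(T.reshape(x, (B, H * W, C)), axis=1)
    if path == "col_forward":
        return T.reshape(T.transpose(x, (0, 2, 1, 3)), (B, H * W, C))
    if path == "col_backward":
        return T.flip(T.reshape(T.transpose(x, (0, 2, 1, 3)), (B, H * W, C)), axis=1)
    raise InvalidParameterError(f"unknown scan path {path!r}")


def _unflatten_t(s: Tensor, path: str, H: int, W: int) -> Tensor:
    """Exact inverse of :func:`_flatten_t`."""
    B, L, C = s.shape
    if L != H * W:
        raise InvalidParameterError(f"sequence length {L} != H*W = {H * W}")
    if path == "row_forward":
        return T.reshape(s, (B, H, W, C))
    if path == "row_backward":
        return T.reshape(T.flip(s, axis=1), (B, H, W, C))
    if path == "col_forward":
        return T.transpose(T.reshape(s, (B, W, H, C)), (0, 2, 1, 3))
    if path == "col_backward":
        return T.transpose(T.reshape(T.flip(s, axis=1), (B, W, H, C)), (0, 2, 1, 3))
    raise InvalidParameterError(f"unknown scan path {path!r}")


def directional_flatten(fmap: np.ndarray, path: str) -> np.ndarray:
    """Flatten an (H, W, C) feature map to an (H·W, C) sequence.

    ``row_forward`` is row-major raster order, ``row_backward`` its
    reversal; ``col_forward``/``col_backward`` are the column-major
    analogues.  Each path is a bijection between grid and sequence index.
    """
    fmap = np.asarray(fmap)
    if fmap.ndim != 3:
        raise InvalidParameterError("feature map must have shape (H, W, C)")
    return _flatten_t(Tensor(fmap[None].astype(np.float64)), path).data[0]


def directional_unflatten(seq: np.ndarray, path: str, H: int, W: int) -> np.ndarray:
    """Restore an (H·W, C) sequence to the (H, W, C) grid (inverse flatten)."""
    seq = np.asarray(seq)
    if seq.ndim != 2:
        raise InvalidParameterError("sequence must have shape (L, C)")
    return _unflatten_t(Tensor(seq[None].astype(np.float64)), path, H, W).data[0]


# ---------------------------------------------------------------------------
# Mamba branch
# ---------------------------------------------------------------------------

def _init_w(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))


class MambaBranch(Module):
    """One gated selective-SSM branch operating on a (B, L, C) sequence.

    Standard design: input projection to an expanded width E = expand·C,
    optional depthwise causal 1-D convolution + SiLU, input-dependent
    (Δ, B, C) projections with softplus-positive Δ, diagonal negative-real
    A = −exp(A_log) initialised to −(n+1), the selective scan, a learnable
    per-channel skip, optional SiLU-gated multiplicative branch, and an
    output projection back to C.  The convolution and gate can be disabled,
    reducing the branch to linear maps around the scan.
    """

    def __init__(self, channels: int, state_dim: int = 16, expand: int = 2,
                 use_conv: bool = True, use_gate: bool = True,
                 conv_kernel: int = 4, zoh_exact: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        C, E, N = channels, expand * channels, state_dim
        self.channels, self.expanded, self.state_dim = C, E, N
        self.use_conv, self.use_gate, self.zoh_exact = use_conv, use_gate, zoh_exact
        self.w_in = Parameter(_init_w(rng, C, E))
        self.b_in = Parameter(np.zeros(E))
        if use_gate:
            self.w_gate = Parameter(_init_w(rng, C, E))
            self.b_gate = Parameter(np.zeros(E))
        if use_conv:
            self.conv_w = Parameter(rng.normal(0.0, 1.0 / np.sqrt(conv_kernel),
                                               size=(conv_kernel, E)))
            self.conv_b = Parameter(np.zeros(E))
        self.w_dt = Parameter(_init_w(rng, E, E))
        # softplus(b_dt) spread over [1e-3, 0.1] so initial steps are small
        dt = np.exp(rng.uniform(np.log(1e-3), np.log(0.1), size=E))
        self.b_dt = Parameter(np.log(np.expm1(dt)))
        self.w_B = Parameter(_init_w(rng, E, N))
        self.w_C = Parameter(_init_w(rng, E, N))
        self.A_log = Parameter(np.log(np.tile(np.arange(1, N + 1, dtype=np.float64),
                                              (E, 1))))
        self.d_skip = Parameter(np.ones(E))
        self.w_out = Parameter(_init_w(rng, E, C))
        self.b_out = Parameter(np.zeros(C))

    def __call__(self, s: Tensor) -> Tensor:
        B, L, C = s.shape
        if C != self.channels:
            raise InvalidParameterError(
                f"branch expects {self.channels} channels, got {C}")
        E, N = self.expanded, self.state_dim
        x = T.linear(s, self.w_in, self.b_in)
        if self.use_conv:
            x = T.silu(T.causal_conv1d(x, self.conv_w, self.conv_b))
        delta = T.softplus(T.linear(x, self.w_dt, self.b_dt))        # (B,L,E)
        Bm = T.linear(x, self.w_B)                                    # (B,L,N)
        Cm = T.linear(x, self.w_C)                                    # (B,L,N)
        A = T.neg(T.exp(self.A_log))                                  # (E,N), < 0
        if self.zoh_exact:
            d4 = T.reshape(delta, (B, L, E, 1))
            A4 = T.reshape(A, (1, 1, E, N))
            Abar = T.exp(T.mul(d4, A4))                               # (B,L,E,N)
            B4 = T.reshape(Bm, (B, L, 1, N))
            Bbar = T.mul(T.div(T.sub(Abar, T.as_tensor(1.0)), A4), B4)
            Bx = T.mul(Bbar, T.reshape(x, (B, L, E, 1)))
            y = ssm_scan_op(Abar, Bx, Cm)                             # (B,L,E)
        else:
            y = fused_ssm_scan_op(x, delta, Bm, Cm, A)                # (B,L,E)
        y = T.add(y, T.mul(x, self.d_skip))
        if self.use_gate:
            y = T.mul(y, T.silu(T.linear(s, self.w_gate, self.b_gate)))
        return T.linear(y, self.w_out, self.b_out)


# ---------------------------------------------------------------------------
# MPV block
# ---------------------------------------------------------------------------

class MPVBlock(Module):
    """Four-direction Mamba block with residual scaling and fusion.

    Forward order:  X_norm = LN(X);  per branch i,
    Y_i = unflatten(Mamba_i(flatten(X_norm, path_i))) + β_i ⊙ X_norm;
    Y_cat = concat(Y_1..Y_4);  Z = Projection(LN(Y_cat)).
    """

    def __init__(self, channels: int, state_dim: int = 16, expand: int = 2,
                 use_conv: bool = True, use_gate: bool = True,
                 conv_kernel: int = 4, zoh_exact: bool = False,
                 rng: np.random.Generator | None = None,
                 paths: tuple[str, ...] = SCAN_PATHS):
        rng = rng or np.random.default_rng()
        if len(paths) != 4 or len(set(paths)) != 4:
            raise InvalidParameterError("MPV requires four distinct scan paths")
        C = channels
        self.channels = C
        self.paths = tuple(paths)
        self.ln1_gamma = Parameter(np.ones(C))
        self.ln1_beta = Parameter(np.zeros(C))
        self.branches = [MambaBranch(C, state_dim=state_dim, expand=expand,
                                     use_conv=use_conv, use_gate=use_gate,
                                     conv_kernel=conv_kernel, zoh_exact=zoh_exact,
                                     rng=rng)
                         for _ in paths]
        self.betas = [Parameter(np.ones(C)) for _ in paths]
        self.ln2_gamma = Parameter(np.ones(4 * C))
        self.ln2_beta = Parameter(np.zeros(4 * C))
        self.w_proj = Parameter(_init_w(rng, 4 * C, C))
        self.b_proj = Parameter(np.zeros(C))

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        if C != self.channels:
            raise InvalidParameterError(
                f"MPV block expects {self.channels} channels, got {C}")
        xn = T.layer_norm(x, self.ln1_gamma, self.ln1_beta)
        ys = []
        for path, branch, beta in zip(self.paths, self.branches, self.betas):
            y = branch(_flatten_t(xn, path))
            y = _unflatten_t(y, path, H, W)
            ys.append(T.add(y, T.mul(xn, beta)))
        cat = T.concat(ys, axis=-1)
        return T.linear(T.layer_norm(cat, self.ln2_gamma, self.ln2_beta),
                        self.w_proj, self.b_proj)


def mpv_forward(fmap: np.ndarray, block: MPVBlock) -> np.ndarray:
    """Run an MPV block on a single (H, W, C) feature map (inference path)."""
    fmap = np.asarray(fmap, dtype=np.float64)
    if fmap.ndim != 3:
        raise InvalidParameterError("feature map must have shape (H, W, C)")
    return block(Tensor(fmap[None])).data[0]
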