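"""The full MFS-Unet: encoder–decoder with MPV blocks at every stage,
Feature-Gating on every skip connection and Supervised Label Rectification
immediately before the output head.

Layout is channels-last (B, H, W, C).  Downsampling halves the spatial
resolution per stage (strided 2×2 convolution, realised as space-to-depth
plus a pointwise linear map, or max pooling); upsampling is a 2×2
transposed convolution (pointwise linear plus depth-to-space) or bilinear
interpolation followed by a pointwise map.  The binary head is a
single-channel 1×1 convolution with a sigmoid; its probability map carries
an implied two-class one-hot view for the SLR error mask (thresholding at
0.5 is the two-class argmax).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _tensor as T
from ._tensor import Module, Parameter, Tensor
from .errors import ConfigurationError, InvalidParameterError
from .metrics import composite_loss, soft_dice
from .mpv import MPVBlock, _init_w
from .fg import FGGate
from .slr import SLRConfig

__all__ = ["NetworkConfig", "SegmentationOutput", "MFSUnet", "build_network",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class NetworkConfig:
    """Architecture and wiring of the network.

    ``depth`` is the number of resolution stages L (input spatial dims must
    be divisible by 2^(L−1)); ``base_width`` scales the per-stage channel
    widths (doubling per stage unless ``widths`` is given).  The ablation
    flags ``use_mpv``/``use_fg``/``use_slr`` reduce the model to plain
    convolutional blocks, ungated skips, or no label rectification.
    """

    in_channels: int = 1
    n_class: int = 1
    depth: int = 4
    base_width: int = 32
    widths: tuple[int, ...] | None = None
    downsample: str = "strided_conv"      # or "max_pool"
    upsample: str = "transposed_conv"     # or "interp_conv"
    ssm_state_dim: int = 16
    ssm_expand: int = 2
    mamba_conv: bool = True
    mamba_gate: bool = True
    mamba_conv_kernel: int = 4
    zoh_exact: bool = False
    use_mpv: bool = True
    use_fg: bool = True
    use_slr: bool = True
    slr: SLRConfig = field(default_factory=SLRConfig)
    fg_upsample: str = "bilinear"
    loss_w_dice: float = 1.0
    loss_w_bce: float = 1.0
    foreground_prior: float = 0.1
    strict_input_range: str = "warn"      # "warn" | "error" | "ignore"
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.n_class != 1:
            raise ConfigurationError(
                "only the binary single-channel sigmoid head is implemented")
        if self.downsample not in ("strided_conv", "max_pool"):
            raise ConfigurationError(f"unknown downsample {self.downsample!r}")
        if self.upsample not in ("transposed_conv", "interp_conv"):
            raise ConfigurationError(f"unknown upsample {self.upsample!r}")
        if isinstance(self.slr, dict):
            self.slr = SLRConfig(**self.slr)
        if self.widths is not None:
            self.widths = tuple(int(w) for w in self.widths)
            if len(self.widths) != self.depth:
                raise ConfigurationError("widths must have one entry per stage")

    def stage_widths(self) -> tuple[int, ...]:
        if self.widths is not None:
            return self.widths
        return tuple(self.base_width * 2 ** i for i in range(self.depth))


@dataclass
class SegmentationOutput:
    """Full-resolution probability map plus the intermediate map SLR used."""

    prob_map: np.ndarray               # (B, H, W)
    aux: np.ndarray | None = None      # intermediate P driving the error mask


class ConvBlock(Module):
    """Plain block for the no-MPV baseline: two depthwise-3×3 + pointwise
    + ReLU units."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.dw1 = Parameter(rng.normal(0, 1 / 3.0, size=(3, 3, channels)))
        self.db1 = Parameter(np.zeros(channels))
        self.pw1 = Parameter(_init_w(rng, channels, channels))
        self.pb1 = Parameter(np.zeros(channels))
        self.dw2 = Parameter(rng.normal(0, 1 / 3.0, size=(3, 3, channels)))
        self.db2 = Parameter(np.zeros(channels))
        self.pw2 = Parameter(_init_w(rng, channels, channels))
        self.pb2 = Parameter(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        x = T.relu(T.linear(T.depthwise_conv2d_3x3(x, self.dw1, self.db1),
                            self.pw1, self.pb1))
        return T.relu(T.linear(T.depthwise_conv2d_3x3(x, self.dw2, self.db2),
                               self.pw2, self.pb2))


class MFSUnet(Module):
    """Encoder–decoder segmentation network (see module docstring)."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = cfg.stage_widths()

        def make_block(c: int) -> Module:
            if cfg.use_mpv:
                return MPVBlock(c, state_dim=cfg.ssm_state_dim,
                                expand=cfg.ssm_expand, use_conv=cfg.mamba_conv,
                                use_gate=cfg.mamba_gate,
                                conv_kernel=cfg.mamba_conv_kernel,
                                zoh_exact=cfg.zoh_exact, rng=rng)
            return ConvBlock(c, rng)

        self.stem_w = Parameter(_init_w(rng, cfg.in_channels, widths[0]))
        self.stem_b = Parameter(np.zeros(widths[0]))
        self.enc_blocks = [make_block(w) for w in widths]
        # downsample i: widths[i] -> widths[i+1]
        self.down_w, self.down_b = [], []
        for i in range(cfg.depth - 1):
            fan_in = 4 * widths[i] if cfg.downsample == "strided_conv" else widths[i]
            self.down_w.append(Parameter(_init_w(rng, fan_in, widths[i + 1])))
            self.down_b.append(Parameter(np.zeros(widths[i + 1])))
        # decoder level i (deep -> shallow): widths[i+1] -> widths[i]
        self.up_w, self.up_b = [], []
        self.fuse_w, self.fuse_b = [], []
        self.gates = []
        self.dec_blocks = []
        for i in range(cfg.depth - 2, -1, -1):
            c_deep, c = widths[i + 1], widths[i]
            fan_out = 4 * c if cfg.upsample == "transposed_conv" else c
            self.up_w.append(Parameter(_init_w(rng, c_deep, fan_out)))
            self.up_b.append(Parameter(np.zeros(fan_out)))
            if cfg.use_fg:
                self.gates.append(FGGate(c, c_deep, max(1, c // 2),
                                         upsample=cfg.fg_upsample, rng=rng))
            self.fuse_w.append(Parameter(_init_w(rng, 2 * c, c)))
            self.fuse_b.append(Parameter(np.zeros(c)))
            self.dec_blocks.append(make_block(c))
        self.head_w = Parameter(_init_w(rng, widths[0], 1))
        # initialise the head bias at the foreground log-odds so early
        # predictions match the class prior instead of p = 0.5
        p = min(max(cfg.foreground_prior, 1e-4), 1 - 1e-4)
        self.head_b = Parameter(np.array([np.log(p / (1 - p))]))
        self._np_dtype = np.dtype(cfg.dtype)
        self.astype(self._np_dtype)

    # -- pieces ----------------------------------------------------------
    def _downsample(self, x: Tensor, i: int) -> Tensor:
        B, H, W, C = x.shape
        if self.cfg.downsample == "strided_conv":
            r = T.reshape(x, (B, H // 2, 2, W // 2, 2, C))
            r = T.transpose(r, (0, 1, 3, 2, 4, 5))
            r = T.reshape(r, (B, H // 2, W // 2, 4 * C))
        else:
            r = T.maxpool2x2(x)
        return T.linear(r, self.down_w[i], self.down_b[i])

    def _upsample(self, x: Tensor, j: int) -> Tensor:
        B, H, W, C = x.shape
        if self.cfg.upsample == "transposed_conv":
            r = T.linear(x, self.up_w[j], self.up_b[j])       # (B,H,W,4c)
            c = r.shape[-1] // 4
            r = T.reshape(r, (B, H, W, 2, 2, c))
            r = T.transpose(r, (0, 1, 3, 2, 4, 5))
            return T.reshape(r, (B, 2 * H, 2 * W, c))
        r = T.bilinear_upsample(x, 2 * H, 2 * W)
        return T.linear(r, self.up_w[j], self.up_b[j])

    def _backbone(self, x: Tensor) -> Tensor:
        """Encoder + decoder up to the final feature map F_dec."""
        cfg = self.cfg
        B, H, W, _ = x.shape
        div = 2 ** (cfg.depth - 1)
        if H % div or W % div:
            raise ConfigurationError(
                f"spatial dims ({H}, {W}) must be divisible by {div}")
        feat = T.linear(x, self.stem_w, self.stem_b)
        skips = []
        for i in range(cfg.depth):
            feat = self.enc_blocks[i](feat)
            if i < cfg.depth - 1:
                skips.append(feat)
                feat = self._downsample(feat, i)
        for j, i in enumerate(range(cfg.depth - 2, -1, -1)):
            skip = skips[i]
            if cfg.use_fg:
                skip, _ = self.gates[j](skip, feat)   # gate taps pre-upsample
            up = self._upsample(feat, j)
            cat = T.concat([skip, up], axis=-1)
            feat = T.linear(cat, self.fuse_w[j], self.fuse_b[j])
            feat = self.dec_blocks[j](feat)
        return feat

    def _head(self, f: Tensor) -> Tensor:
        return T.linear(f, self.head_w, self.head_b)

    def _prepare_image(self, image: np.ndarray) -> Tensor:
        image = np.asarray(image, dtype=self._np_dtype)
        if image.ndim == 2:
            image = image[None]
        if image.ndim == 3:
            image = image[..., None]
        if image.shape[-1] != self.cfg.in_channels:
            raise InvalidParameterError(
                f"expected {self.cfg.in_channels} input channels, "
                f"got {image.shape[-1]}")
        if image.max() > 1.0 + 1e-6 or image.min() < -1e-6:
            msg = "input image is not normalised to [0, 1]"
            if self.cfg.strict_input_range == "error":
                raise InvalidParameterError(msg)
            if self.cfg.strict_input_range == "warn":
                warnings.warn(msg, RuntimeWarning, stacklevel=3)
        return Tensor(image)

    # -- public API -------------------------------------------------------
    def forward_train(self, image: np.ndarray, label: np.ndarray
                      ) -> tuple[SegmentationOutput, dict]:
        """One supervised pass: SLR-rectified features feed the output head.

        ``label`` is a (B, H, W) or (H, W) binary mask.  Returns the
        probability map plus a loss dict with the Dice and BCE components
        (``total`` is the differentiable composite scalar).
        """
        x = self._prepare_image(image)
        label = np.asarray(label, dtype=self._np_dtype)
        if label.ndim == 2:
            label = label[None]
        if label.shape != x.shape[:3]:
            raise InvalidParameterError(
                f"label shape {label.shape} does not match image {x.shape[:3]}")
        f_dec = self._backbone(x)
        aux = None
        if self.cfg.use_slr and self.cfg.slr.enabled:
            # hard error mask from the (gradient-blocked) intermediate prediction
            p_int = 1.0 / (1.0 + np.exp(-self._head(f_dec).data[..., 0]))
            pred = (p_int >= 0.5).astype(self._np_dtype)
            m = (pred != label).astype(self._np_dtype)[..., None]
            lam, gam = self.cfg.slr.lam, self.cfg.slr.gam
            mixed = (f_dec * (1.0 - m)) * (1.0 - lam) - (f_dec * m) * (lam * gam)
            f_dec = f_dec + mixed
            aux = p_int
        logits = self._head(f_dec)
        prob = T.sigmoid(logits)
        y = T.as_tensor(label[..., None])
        dice_loss = 1.0 - soft_dice(prob, y)
        bce = composite_loss(prob, y, w_dice=0.0, w_bce=1.0)
        total = T.scale(dice_loss, self.cfg.loss_w_dice) + \
            T.scale(bce, self.cfg.loss_w_bce)
        out = SegmentationOutput(prob_map=prob.data[..., 0], aux=aux)
        return out, {"dice": dice_loss, "bce": bce, "total": total}

    def forward_infer(self, image: np.ndarray) -> SegmentationOutput:
        """Label-free deterministic pass; SLR is a strict pass-through."""
        x = self._prepare_image(image)
        logits = self._head(self._backbone(x))
        return SegmentationOutput(prob_map=(1.0 / (1.0 + np.exp(-logits.data[..., 0]))))


def build_network(cfg: NetworkConfig) -> MFSUnet:
    """Construct a seeded network; parameter count is a pure function of cfg."""
    return MFSUnet(cfg)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _cfg_to_dict(cfg: NetworkConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def save_checkpoint(net: MFSUnet, path: str | Path,
                    extra: dict[str, np.ndarray] | None = None) -> None:
    """Write weights (npz) plus a JSON config sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param/{k}": v for k, v in net.state_dict().items()}
    for k, v in (extra or {}).items():
        arrays[f"extra/{k}"] = np.asarray(v)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(
        json.dumps(_cfg_to_dict(net.cfg), indent=2))


def load_checkpoint(path: str | Path) -> tuple[MFSUnet, dict[str, np.ndarray]]:
    """Rebuild the network from its sidecar config and restore weights."""
    path = Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    if cfg_dict.get("widths") is not None:
        cfg_dict["widths"] = tuple(cfg_dict["widths"])
    cfg = NetworkConfig(**cfg_dict)
    net = build_network(cfg)
    with np.load(path.with_suffix(".npz")) as data:
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
        extra = {k[len("extra/"):]: data[k] for k in data.files
                 if k.startswith("extra/")}
    net.load_state_dict(state)
    return net, extra
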