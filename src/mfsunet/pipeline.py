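"""Training and evaluation orchestration.

Implements the experimental protocol around the network: resize-and-scale
preprocessing, flip/rotate/scale augmentation applied identically to image
and masks, AdamW with plateau-based learning-rate halving (50% after 10
stagnant validation epochs), best-on-validation checkpointing, per-sample
metric reporting, the component-ablation driver and the (λ, γ) grid-search
driver.  Patient-level split hygiene is enforced: evaluation refuses to
run when an evaluation patient id appears in the training manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import (ConfigurationError, InvalidParameterError, LeakageError,
                     NumericError, TrainingDivergedError)
from .metrics import composite_loss, evaluate_masks, metric_table
from .network import (MFSUnet, NetworkConfig, build_network, load_checkpoint,
                      save_checkpoint)
from .optim import AdamW, ReduceLROnPlateau
from .phantom import SegmentationSample
from .slr import slr_grid_search

__all__ = ["TrainConfig", "TrainResult", "preprocess", "augment", "train",
           "evaluate", "ablation_suite", "gridsearch", "check_split_hygiene"]


@dataclass
class TrainConfig:
    """Optimisation protocol.

    Defaults follow the full-scale recipe (300 epochs, batch 8, AdamW at
    lr 1e-4 with weight decay 1e-5, halve the lr after 10 stagnant
    validation epochs); smoke-scale runs override epochs/lr explicitly.
    """

    epochs: int = 300
    batch_size: int = 8
    lr: float = 1e-4
    weight_decay: float = 1e-5
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    augment: bool = True
    flip: bool = True
    rot_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    label_source: str = "mask"          # or "noisy_mask"
    early_stop_dice: float | None = None
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.plateau_patience < 1:
            raise ConfigurationError("epochs and patience must be >= 1")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ConfigurationError("plateau factor must lie in (0, 1)")
        if self.label_source not in ("mask", "noisy_mask"):
            raise ConfigurationError(f"unknown label source {self.label_source!r}")
        if self.device != "cpu":
            raise ConfigurationError("only cpu execution is supported")


@dataclass
class TrainResult:
    net: MFSUnet
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float
    lr_events: list[tuple[int, float]]


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------

def preprocess(image, size: int = 256) -> np.ndarray:
    """Resize a grayscale raster to (size, size) and scale into [0, 1].

    Accepts a numpy array or an image path; integer inputs are divided by
    their dtype maximum, floats are assumed pre-scaled (and only resized).
    """
    if isinstance(image, (str, Path)):
        try:
            image = np.asarray(Image.open(image).convert("L"))
        except Exception as exc:
            raise IOError(f"cannot read image file {image!r}: {exc}") from exc
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidParameterError("expected a 2-D grayscale image")
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float64) / np.iinfo(image.dtype).max
    else:
        image = image.astype(np.float64)
    if image.shape != (size, size):
        pil = Image.fromarray(image)
        image = np.asarray(pil.resize((size, size), Image.BILINEAR),
                           dtype=np.float64)
    return np.clip(image, 0.0, 1.0)


def _affine_pair(arr: np.ndarray, matrix: np.ndarray, order: int) -> np.ndarray:
    center = (np.asarray(arr.shape) - 1) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                    mode="constant", cval=arr.min() if order else 0)


def augment(sample: SegmentationSample, rng: np.random.Generator,
            flip: bool = True, rot_deg: float = 15.0,
            scale_range: tuple[float, float] = (0.9, 1.1)
            ) -> SegmentationSample:
    """Random horizontal flip, rotation and isotropic scaling.

    One transform is drawn and applied to the image (bilinear) and to both
    masks (nearest neighbour, so they stay binary).  Degenerate settings
    (rot_deg = 0, scale_range = (1, 1), flip = False) give the identity.
    """
    theta = np.deg2rad(rng.uniform(-rot_deg, rot_deg)) if rot_deg > 0 else 0.0
    s = rng.uniform(*scale_range) if scale_range != (1.0, 1.0) else 1.0
    do_flip = flip and rng.uniform() < 0.5
    if theta == 0.0 and s == 1.0 and not do_flip:
        return sample
    c, sn = np.cos(theta), np.sin(theta)
    # inverse map for ndimage (output -> input coordinates)
    inv = np.array([[c, -sn], [sn, c]]) / s
    img = sample.image
    mask = sample.mask
    noisy = sample.noisy_mask
    if do_flip:
        img, mask, noisy = img[:, ::-1], mask[:, ::-1], noisy[:, ::-1]
    img = _affine_pair(np.ascontiguousarray(img), inv, order=1)
    mask = _affine_pair(np.ascontiguousarray(mask.astype(np.float64)),
                        inv, order=0) > 0.5
    noisy = _affine_pair(np.ascontiguousarray(noisy.astype(np.float64)),
                         inv, order=0) > 0.5
    return replace(sample, image=np.clip(img, 0.0, 1.0), mask=mask,
                   noisy_mask=noisy)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _stack(samples: list[SegmentationSample], label_source: str
           ) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples])
    labs = np.stack([getattr(s, label_source).astype(np.float64)
                     for s in samples])
    return imgs, labs


def _validate(net: MFSUnet, samples: list[SegmentationSample],
              batch_size: int) -> tuple[float, float]:
    """Mean composite loss and mean hard Dice on a sample list."""
    losses, dices = [], []
    for i in range(0, len(samples), batch_size):
        batch = samples[i:i + batch_size]
        imgs, labs = _stack(batch, "mask")
        prob = net.forward_infer(imgs).prob_map
        losses.append(composite_loss(prob.astype(np.float64), labs)
                      * len(batch))
        for p, y in zip(prob, labs):
            dices.append(evaluate_masks(p >= 0.5, y > 0.5).dice)
    return float(np.sum(losses) / len(samples)), float(np.mean(dices))


def train(cfg: TrainConfig, net_cfg: NetworkConfig,
          train_samples: list[SegmentationSample],
          val_samples: list[SegmentationSample],
          resume_from: str | Path | None = None,
          checkpoint_path: str | Path | None = None) -> TrainResult:
    """Seeded training run with plateau annealing and best-on-val tracking.

    Fully reproducible on a single device: the same (cfg, net_cfg, data)
    produce the same loss trajectory, and resuming from a checkpoint
    continues the interrupted trajectory exactly.
    """
    check_split_hygiene({"train": train_samples, "val": val_samples})
    rng = np.random.default_rng(cfg.seed)
    start_epoch = 0
    history_rows: list[dict] = []
    best_state = None
    best_dice, best_epoch = -1.0, -1
    if resume_from is not None:
        net, extra = load_checkpoint(resume_from)
        state = json.loads(str(extra["train_state_json"]))
        opt = AdamW(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        opt.load_state_dict({k: extra[f"opt_{k}"] for k in state["opt_keys"]})
        sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                  patience=cfg.plateau_patience)
        sched.best = state["sched_best"]
        sched.num_bad = state["sched_num_bad"]
        sched.epoch = state["epoch"]
        sched.events = [tuple(e) for e in state["lr_events"]]
        rng.bit_generator.state = state["rng_state"]
        start_epoch = state["epoch"]
        history_rows = state["history"]
        best_dice = state["best_dice"]
        best_epoch = state["best_epoch"]
        best_state = {k[len("best_"):]: extra[k] for k in extra
                      if k.startswith("best_")}
    else:
        net = build_network(net_cfg)
        opt = AdamW(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                  patience=cfg.plateau_patience)

    n = len(train_samples)
    for epoch in range(start_epoch + 1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            batch = [train_samples[j] for j in idx]
            if cfg.augment:
                batch = [augment(s, rng, flip=cfg.flip, rot_deg=cfg.rot_deg,
                                 scale_range=cfg.scale_range) for s in batch]
            imgs, labs = _stack(batch, cfg.label_source)
            opt.zero_grad()
            ids = [s.sample_id or s.patient_id for s in batch]
            try:
                _, losses = net.forward_train(imgs, labs)
                loss_val = float(losses["total"].data)
            except NumericError as exc:
                raise TrainingDivergedError(
                    f"non-finite values at epoch {epoch}, samples {ids}: "
                    f"{exc}") from exc
            if not np.isfinite(loss_val):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, samples {ids}")
            losses["total"].backward()
            opt.step()
            epoch_loss += loss_val * len(idx)
        val_loss, val_dice = _validate(net, val_samples, cfg.batch_size)
        sched.step(val_loss)
        history_rows.append({"epoch": epoch, "train_loss": epoch_loss / n,
                             "val_loss": val_loss, "val_dice": val_dice,
                             "lr": opt.lr})
        if val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_state = net.state_dict()
        if checkpoint_path is not None:
            _save_train_checkpoint(net, opt, sched, rng, history_rows,
                                   best_dice, best_epoch, best_state or {},
                                   checkpoint_path)
        if cfg.early_stop_dice is not None and val_dice >= cfg.early_stop_dice:
            break
    if best_state:
        net.load_state_dict(best_state)
    return TrainResult(net=net, history=pd.DataFrame(history_rows),
                       best_epoch=best_epoch, best_val_dice=best_dice,
                       lr_events=list(sched.events))


def _save_train_checkpoint(net, opt, sched, rng, history, best_dice,
                           best_epoch, best_state, path) -> None:
    opt_state = opt.state_dict()
    extra = {f"opt_{k}": v for k, v in opt_state.items()}
    for k, v in best_state.items():
        extra[f"best_{k}"] = v
    extra["train_state_json"] = np.array(json.dumps({
        "epoch": sched.epoch,
        "sched_best": sched.best,
        "sched_num_bad": sched.num_bad,
        "lr_events": sched.events,
        "rng_state": rng.bit_generator.state,
        "history": history,
        "best_dice": best_dice,
        "best_epoch": best_epoch,
        "opt_keys": list(opt_state.keys()),
    }))
    save_checkpoint(net, path, extra=extra)


# ---------------------------------------------------------------------------
# evaluation and split hygiene
# ---------------------------------------------------------------------------

def check_split_hygiene(splits: dict[str, list[SegmentationSample]]) -> None:
    """Raise :class:`LeakageError` if any patient id spans two splits."""
    names = list(splits)
    pid_sets = {k: {s.patient_id for s in v} for k, v in splits.items()}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = pid_sets[a] & pid_sets[b]
            if shared:
                raise LeakageError(
                    f"patient ids shared between {a!r} and {b!r}: "
                    f"{sorted(shared)[:5]}")


def evaluate(net: MFSUnet | str | Path,
             samples: list[SegmentationSample],
             train_patient_ids: set[str] | None = None,
             threshold: float = 0.5, batch_size: int = 8,
             csv_path: str | Path | None = None) -> pd.DataFrame:
    """Per-sample metric table (Dice/IoU/precision/SE/HD95) plus summary.

    If ``train_patient_ids`` is supplied, any overlap with the evaluated
    patients is a hard :class:`LeakageError`.
    """
    if isinstance(net, (str, Path)):
        net, _ = load_checkpoint(net)
    if train_patient_ids is not None:
        shared = {s.patient_id for s in samples} & set(train_patient_ids)
        if shared:
            raise LeakageError(
                f"evaluation patients found in the training manifest: "
                f"{sorted(shared)[:5]}")
    reports, ids = [], []
    for i in range(0, len(samples), batch_size):
        batch = samples[i:i + batch_size]
        imgs, labs = _stack(batch, "mask")
        prob = net.forward_infer(imgs).prob_map
        for s, p, y in zip(batch, prob, labs):
            reports.append(evaluate_masks(p >= threshold, y > 0.5))
            ids.append(s.sample_id or s.patient_id)
    table = metric_table(reports, ids)
    if csv_path is not None:
        table.to_csv(csv_path)
    return table


# ---------------------------------------------------------------------------
# ablations and grid search
# ---------------------------------------------------------------------------

_ABLATIONS = (
    ("encoder-decoder", {"use_mpv": False, "use_fg": False, "use_slr": False}),
    ("w/o F&S", {"use_mpv": True, "use_fg": False, "use_slr": False}),
    ("w/o S", {"use_mpv": True, "use_fg": True, "use_slr": False}),
    ("full", {"use_mpv": True, "use_fg": True, "use_slr": True}),
)


def ablation_suite(train_cfg: TrainConfig, net_cfg: NetworkConfig,
                   train_samples, val_samples, test_samples) -> pd.DataFrame:
    """Train the component-ablation ladder under identical seeds.

    Rows: plain encoder-decoder, MPV only ("w/o F&S"), MPV+FG ("w/o S"),
    and the full model; columns report parameter count and test Dice/IoU.
    """
    rows = []
    for name, flags in _ABLATIONS:
        cfg_i = replace(net_cfg, **flags)
        res = train(train_cfg, cfg_i, train_samples, val_samples)
        table = evaluate(res.net, test_samples)
        body = table.iloc[:-1]
        rows.append({
            "variant": name,
            "n_params": res.net.n_parameters(),
            "dice": float(np.mean(body["dice"].astype(float))),
            "iou": float(np.mean(body["iou"].astype(float))),
            "val_dice": res.best_val_dice,
        })
    return pd.DataFrame(rows)


def gridsearch(train_cfg: TrainConfig, net_cfg: NetworkConfig,
               train_samples, val_samples,
               lam_grid=None, gam_grid=None):
    """(λ, γ) sweep of the label-rectification hyperparameters using real
    training runs; returns (table, best_pair)."""
    from .slr import GAMMA_GRID, LAMBDA_GRID

    def train_fn(lam: float, gam: float) -> float:
        cfg_i = replace(net_cfg, slr=replace(net_cfg.slr, lam=lam, gam=gam))
        return train(train_cfg, cfg_i, train_samples, val_samples).best_val_dice

    return slr_grid_search(train_fn,
                           lam_grid or LAMBDA_GRID,
                           gam_grid or GAMMA_GRID)
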