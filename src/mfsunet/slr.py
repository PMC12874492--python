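"""Supervised Label Rectification (SLR).

During training, the current prediction is compared against the (possibly
imperfect) label to obtain a hard per-pixel error mask M.  Decoder
features are partitioned by M and recombined punitively,

    F_wrong  = F_dec ⊙ M,            F_correct = F_dec ⊙ (1 − M),
    F_mixed  = (1 − λ)·F_correct − λ·γ·F_wrong,
    F_out    = F_dec + F_mixed,

which damps feature responses in disagreement regions (boundary-ambiguous
pixels, annotation jitter) while boosting agreeing regions.  The mask is a
constant for backpropagation; at inference the operator is a pass-through
since no label exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._tensor import Tensor, as_tensor
from .errors import InvalidParameterError, NumericError

__all__ = [
    "ProbabilityMap", "LabelMask", "ErrorMask", "SLRConfig",
    "prediction_mask", "error_mask", "rectify", "slr_grid_search",
    "LAMBDA_GRID", "GAMMA_GRID",
]

#: default hyperparameter search grids for (λ, γ)
LAMBDA_GRID: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
GAMMA_GRID: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass
class ProbabilityMap:
    """Per-pixel class scores P of shape (H, W, N_class), values in [0, 1]."""

    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 3 or self.P.shape[2] < 2:
            raise InvalidParameterError("P must have shape (H, W, N_class>=2)")
        if np.isnan(self.P).any():
            raise NumericError("probability map contains NaN")
        if (self.P < -1e-6).any() or (self.P > 1 + 1e-6).any():
            raise InvalidParameterError("probabilities must lie in [0, 1]")


@dataclass
class LabelMask:
    """Integer class map Y of shape (H, W)."""

    Y: np.ndarray
    n_class: int = 2

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise InvalidParameterError("label mask must have shape (H, W)")
        if not np.issubdtype(self.Y.dtype, np.integer):
            if not np.array_equal(self.Y, self.Y.astype(np.int64)):
                raise InvalidParameterError("label mask must be integer-valued")
            self.Y = self.Y.astype(np.int64)
        if (self.Y < 0).any() or (self.Y >= self.n_class).any():
            raise InvalidParameterError("labels outside [0, n_class)")

    @property
    def Y_ohe(self) -> np.ndarray:
        """One-hot expansion, shape (H, W, n_class)."""
        return np.eye(self.n_class, dtype=np.float64)[self.Y]


@dataclass
class ErrorMask:
    """Binary disagreement map M of shape (H, W, 1)."""

    M: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim == 2:
            self.M = self.M[:, :, None]
        if self.M.shape[-1] != 1:
            raise InvalidParameterError("error mask must have shape (H, W, 1)")
        if not np.isin(self.M, (0.0, 1.0)).all():
            raise InvalidParameterError("error mask must be binary")


@dataclass
class SLRConfig:
    """λ weights the correct/wrong mix; γ scales the penalty on wrong pixels."""

    lam: float = 0.5
    gam: float = 1.0
    share_head: bool = True
    enabled: bool = True

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise InvalidParameterError("lambda must lie in [0, 1]")
        if self.gam <= 0.0:
            raise InvalidParameterError("gamma must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def prediction_mask(P: ProbabilityMap | np.ndarray) -> LabelMask:
    """Hard class assignment by per-pixel argmax (lowest index wins ties)."""
    if not isinstance(P, ProbabilityMap):
        P = ProbabilityMap(np.asarray(P))
    return LabelMask(np.argmax(P.P, axis=2).astype(np.int64),
                     n_class=P.P.shape[2])


def error_mask(pred: LabelMask, truth: LabelMask) -> ErrorMask:
    """M(i,j) = 1 exactly where the predicted class differs from the label."""
    if pred.Y.shape != truth.Y.shape:
        raise InvalidParameterError(
            f"shape mismatch: {pred.Y.shape} vs {truth.Y.shape}")
    return ErrorMask((pred.Y != truth.Y).astype(np.float64))


def rectify(F_dec, M: ErrorMask | np.ndarray, cfg: SLRConfig):
    """Punitive feature mix with residual recombination.

    Accepts a numpy array (H, W, C) or a tape :class:`Tensor` with leading
    batch axis; the mask is broadcast across channels and treated as a
    constant for gradients.  Wherever M = 0 the output is (2−λ)·F_dec;
    wherever M = 1 it is (1−λγ)·F_dec.
    """
    if not isinstance(cfg, SLRConfig):
        raise InvalidParameterError("cfg must be an SLRConfig")
    m = M.M if isinstance(M, ErrorMask) else ErrorMask(np.asarray(M)).M
    if isinstance(F_dec, Tensor):
        if F_dec.shape[-3:-1] != m.shape[:2]:
            raise InvalidParameterError("mask spatial dims do not match features")
        mt = as_tensor(m)
        one_minus = as_tensor(1.0 - m)
        mixed = (F_dec * one_minus) * (1.0 - cfg.lam) - (F_dec * mt) * (cfg.lam * cfg.gam)
        return F_dec + mixed
    F = np.asarray(F_dec, dtype=np.float64)
    if F.ndim != 3 or F.shape[:2] != m.shape[:2]:
        raise InvalidParameterError("features must be (H, W, C) matching the mask")
    mixed = (1.0 - cfg.lam) * (F * (1.0 - m)) - cfg.lam * cfg.gam * (F * m)
    return F + mixed


def slr_grid_search(train_fn: Callable[[float, float], float],
                    lam_grid: Sequence[float] = LAMBDA_GRID,
                    gam_grid: Sequence[float] = GAMMA_GRID,
                    ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Exhaustive (λ, γ) search.

    ``train_fn(lam, gam)`` must return a validation Dice score (higher is
    better) and be deterministic given its own seeding.  A failing cell is
    recorded with a NaN score and the error message rather than aborting
    the sweep.  Returns the full table and the arg-max pair.
    """
    lam_grid = tuple(lam_grid)
    gam_grid = tuple(gam_grid)
    if not lam_grid or not gam_grid:
        raise InvalidParameterError("search grids must be non-empty")
    rows = []
    for lam in lam_grid:
        for gam in gam_grid:
            try:
                dice = float(train_fn(lam, gam))
                err = ""
            except Exception as exc:  # a failed cell is data, not fatal
                dice, err = np.nan, f"{type(exc).__name__}: {exc}"
            rows.append({"lam": lam, "gam": gam, "dice": dice, "error": err})
    table = pd.DataFrame(rows)
    if table["dice"].notna().any():
        best = table.loc[table["dice"].idxmax()]
        best_pair = (float(best["lam"]), float(best["gam"]))
    else:
        raise RuntimeError("every grid cell failed; no optimum available")
    return table, best_pair
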