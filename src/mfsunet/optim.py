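"""AdamW optimizer and plateau-based learning-rate annealing."""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter
from .errors import InvalidParameterError

__all__ = ["AdamW", "ReduceLROnPlateau"]


class AdamW:
    """Decoupled-weight-decay Adam on the engine's parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        if lr <= 0:
            raise InvalidParameterError("learning rate must be positive")
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict:
        out = {"t": np.array(self.t), "lr": np.array(self.lr)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m.copy()
            out[f"v{i}"] = v.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.asarray(state[f"m{i}"]).copy() for i in range(len(self.params))]
        self.v = [np.asarray(state[f"v{i}"]).copy() for i in range(len(self.params))]


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate after ``patience`` epochs
    without improvement of the monitored validation loss."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5,
                 patience: int = 10, min_delta: float = 0.0):
        if not (0.0 < factor < 1.0):
            raise InvalidParameterError("factor must lie in (0, 1)")
        if patience < 1:
            raise InvalidParameterError("patience must be >= 1")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best: float | None = None
        self.num_bad = 0
        self.epoch = 0
        self.events: list[tuple[int, float]] = []   # (epoch, new lr)

    def step(self, metric: float) -> bool:
        """Feed one epoch's validation metric; returns True if lr was reduced."""
        self.epoch += 1
        if self.best is None or metric < self.best - self.min_delta:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr *= self.factor
            self.events.append((self.epoch, self.optimizer.lr))
            self.num_bad = 0
            return True
        return False
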