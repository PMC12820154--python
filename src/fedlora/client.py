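"""Local client training under the FedProx objective.

Each client minimizes  F_k(w) + (mu/2) ||w - w_global||^2  over its trainable
tensors with AdamW and a cosine-annealed learning rate, where F_k is the mean
cross-entropy on the client's shard.  mu = 0 recovers plain FedAvg local
training.  The proximal norm runs over the trainable (exchanged) tensors
only, anchored at the weights received from the server at round start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff
from .data import ClientShard, preprocess_batch
from .errors import DivergenceError, EmptyDataError, IncompatibilityError
from .vit import ModelState

__all__ = [
    "FedProxConfig",
    "ClientUpdate",
    "fedprox_loss",
    "local_empirical_risk",
    "local_train",
    "AdamW",
]


@dataclass(frozen=True)
class FedProxConfig:
    mu: float = 0.5
    local_epochs: int = 1
    batch_size: int = 8
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass
class ClientUpdate:
    weights: dict[str, np.ndarray]
    n_i: int
    client_id: int
    local_loss_trace: list[float] = field(default_factory=list)


def fedprox_loss(
    ce: float, w: dict[str, np.ndarray], w_global: dict[str, np.ndarray], mu: float
) -> float:
    """ce + (mu/2) * sum ||w - w_global||^2 over all shared tensors."""
    if set(w) != set(w_global):
        raise IncompatibilityError(
            f"weight key mismatch: {sorted(set(w) ^ set(w_global))}"
        )
    sq = sum(float(((w[k] - w_global[k]) ** 2).sum()) for k in w)
    return float(ce) + 0.5 * mu * sq


def local_empirical_risk(model: ModelState, shard: ClientShard) -> float:
    """F_k(w): mean cross-entropy of the model over the shard (eval mode)."""
    if shard.n_i == 0:
        raise EmptyDataError("shard is empty")
    x = preprocess_batch(shard.images)
    logits, _ = autodiff.model_forward(model, x, train=False)
    ce, _ = autodiff.softmax_cross_entropy(logits, shard.labels)
    return ce


class AdamW:
    """Decoupled-weight-decay Adam over a named tensor set."""

    def __init__(self, keys, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.wd * params[k]
            )


def cosine_lr(base_lr: float, epoch: int, t_max: int, eta_min: float = 0.0) -> float:
    if t_max <= 0:
        return base_lr
    return eta_min + 0.5 * (base_lr - eta_min) * (1 + math.cos(math.pi * epoch / t_max))


def local_train(
    shard: ClientShard, global_model: ModelState, cfg: FedProxConfig
) -> ClientUpdate:
    """Run local FedProx epochs starting from the received global model.

    Only trainable tensors move; frozen base weights are untouched.  The
    returned update carries the full post-training trainable set, the local
    sample count n_i, and the per-step FedProx loss trace.  Deterministic for
    a fixed (cfg.seed, client_id).
    """
    if shard.n_i == 0:
        raise EmptyDataError(f"client {shard.client_id} has no data")
    model = global_model.copy()
    keys = model.trainable_keys()
    anchor = {k: model.params[k].copy() for k in keys}
    rng = np.random.default_rng([cfg.seed, shard.client_id])
    opt = AdamW(keys, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    trace: list[float] = []
    for epoch in range(cfg.local_epochs):
        lr = cosine_lr(cfg.learning_rate, epoch, cfg.local_epochs)
        order = rng.permutation(shard.n_i)
        for start in range(0, shard.n_i, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = preprocess_batch(shard.images[idx])
            y = shard.labels[idx]
            ce, loss, grads = autodiff.loss_and_grads(
                model, x, y, mu=cfg.mu, anchor=anchor, train=True, rng=rng
            )
            if not math.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss on client {shard.client_id}"
                )
            opt.step(model.params, grads, lr=lr)
            trace.append(loss)
    weights = {k: model.params[k].copy() for k in keys}
    return ClientUpdate(
        weights=weights, n_i=shard.n_i, client_id=shard.client_id, local_loss_trace=trace
    )
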