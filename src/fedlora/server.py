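"""Federated orchestration: client selection, broadcast, sample-weighted
aggregation, per-round payload accounting and convergence tracking.

One communication round is broadcast -> local training on the selected
clients -> aggregation w_global <- sum_i (n_i / n) w_i -> global evaluation.
Four strategy arms are supported: fedavg and fedprox exchange the full
weight set; fedavg_lora and fedprox_lora exchange only the adapter state.
LoRA A and B factors are averaged entrywise (note mean(A) mean(B) is not
mean(A B) in general; entrywise averaging is what keeps the aggregation rule
linear in the exchanged tensors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff
from .client import ClientUpdate, FedProxConfig, local_train
from .data import ClientShard, preprocess_batch
from .errors import ConfigurationError, EmptyDataError, IncompatibilityError
from .lora import LoRAConfig, inject_lora, load_adapter_state
from .vit import ModelState, ViTConfig, build_model

__all__ = [
    "FederationConfig",
    "RoundLog",
    "GlobalState",
    "aggregate",
    "select_clients",
    "run_round",
    "run_federated_training",
    "convergence_rounds",
    "evaluate_global",
]

STRATEGIES = ("fedavg", "fedavg_lora", "fedprox", "fedprox_lora")


@dataclass(frozen=True)
class FederationConfig:
    n_clients: int = 10
    client_fraction: float = 1.0
    rounds: int = 20
    strategy: str = "fedprox_lora"
    mu: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.client_fraction <= 1.0:
            raise ConfigurationError("client_fraction must be in (0, 1]")
        if self.n_clients < 1:
            raise ConfigurationError("need at least one client")
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")

    @property
    def uses_lora(self) -> bool:
        return self.strategy.endswith("_lora")

    @property
    def effective_mu(self) -> float:
        return self.mu if self.strategy.startswith("fedprox") else 0.0


@dataclass
class RoundLog:
    round: int
    selected_clients: list[int]
    client_sizes: dict[int, int]
    uplink_bytes: int
    downlink_bytes: int
    accuracy: float
    mean_local_loss: float

    @property
    def total_bytes(self) -> int:
        return self.uplink_bytes + self.downlink_bytes


@dataclass
class GlobalState:
    model: ModelState
    round: int = 0
    history: list[RoundLog] = field(default_factory=list)


def exchanged_keys(model: ModelState) -> list[str]:
    """The tensor set a client transmits: trainable tensors for LoRA arms,
    everything for full-model arms."""
    if model.lora is not None:
        return model.trainable_keys()
    return sorted(model.params)


def aggregate(updates: list[ClientUpdate]) -> dict[str, np.ndarray]:
    """Sample-weighted average, w = sum_i (n_i / n) w_i, per tensor."""
    if not updates:
        raise EmptyDataError("no client updates to aggregate")
    keys = set(updates[0].weights)
    for u in updates:
        if set(u.weights) != keys:
            raise IncompatibilityError("client updates do not share tensor keys")
    n = sum(u.n_i for u in updates)
    out: dict[str, np.ndarray] = {}
    for k in keys:
        acc = np.zeros_like(updates[0].weights[k], dtype=np.float64)
        for u in updates:
            acc += (u.n_i / n) * u.weights[k]
        out[k] = acc.astype(updates[0].weights[k].dtype)
    return out


def select_clients(K: int, fraction: float, round_index: int, seed: int) -> list[int]:
    """Uniform sampling without replacement; deterministic per (round, seed)."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("fraction must be in (0, 1]")
    m = max(1, int(round(fraction * K)))
    if m >= K:
        return list(range(K))
    rng = np.random.default_rng([seed, round_index])
    return sorted(rng.choice(K, size=m, replace=False).tolist())


def evaluate_global(model: ModelState, images: np.ndarray, labels: np.ndarray) -> float:
    """Argmax accuracy of the global model on a held-out set."""
    x = preprocess_batch(images)
    logits, _ = autodiff.model_forward(model, x, train=False)
    return float((logits.argmax(axis=1) == labels).mean())


def payload_bytes(model: ModelState, bit_precision: int = 32) -> int:
    """Per-client, per-direction payload for the exchanged tensor set."""
    count = sum(model.params[k].size for k in exchanged_keys(model))
    return count * bit_precision // 8


def run_round(
    state: GlobalState,
    shards: list[ClientShard],
    fed_cfg: FederationConfig,
    client_cfg: FedProxConfig,
    test_images: np.ndarray,
    test_labels: np.ndarray,
) -> GlobalState:
    """One communication round; appends a RoundLog and increments the round."""
    selected = select_clients(
        fed_cfg.n_clients, fed_cfg.client_fraction, state.round, fed_cfg.seed
    )
    per_client = payload_bytes(state.model)
    updates: list[ClientUpdate] = []
    for cid in selected:
        shard = shards[cid]
        if shard.n_i == 0:
            continue
        cfg = FedProxConfig(
            mu=fed_cfg.effective_mu,
            local_epochs=client_cfg.local_epochs,
            batch_size=client_cfg.batch_size,
            learning_rate=client_cfg.learning_rate,
            weight_decay=client_cfg.weight_decay,
            seed=int(np.random.SeedSequence([fed_cfg.seed, state.round]).generate_state(1)[0] % (2**31)),
        )
        updates.append(local_train(shard, state.model, cfg))
    if not updates:
        raise EmptyDataError(f"round {state.round}: every client was skipped")
    new_weights = aggregate(updates)
    if state.model.lora is not None:
        load_adapter_state(state.model, new_weights)
    else:
        for k, v in new_weights.items():
            state.model.params[k] = v
    acc = evaluate_global(state.model, test_images, test_labels)
    mean_loss = float(
        np.mean([u.local_loss_trace[-1] for u in updates if u.local_loss_trace])
    )
    log = RoundLog(
        round=state.round + 1,
        selected_clients=selected,
        client_sizes={u.client_id: u.n_i for u in updates},
        uplink_bytes=per_client * len(updates),
        downlink_bytes=per_client * len(selected),
        accuracy=acc,
        mean_local_loss=mean_loss,
    )
    state.history.append(log)
    state.round += 1
    return state


def run_federated_training(
    fed_cfg: FederationConfig,
    shards: list[ClientShard],
    test_images: np.ndarray,
    test_labels: np.ndarray,
    vit_cfg: ViTConfig,
    lora_cfg: Optional[LoRAConfig] = None,
    client_cfg: Optional[FedProxConfig] = None,
    initial_model: Optional[ModelState] = None,
) -> GlobalState:
    """Full multi-round simulation for one strategy arm.

    ``initial_model`` lets every arm start from a shared (e.g. pretrained)
    backbone, the setting LoRA fine-tuning presumes.
    """
    if len(shards) != fed_cfg.n_clients:
        raise ConfigurationError(
            f"{len(shards)} shards for {fed_cfg.n_clients} clients"
        )
    client_cfg = client_cfg or FedProxConfig(mu=fed_cfg.effective_mu)
    model = initial_model.copy() if initial_model is not None else build_model(vit_cfg, seed=fed_cfg.seed)
    if fed_cfg.uses_lora:
        model = inject_lora(model, lora_cfg or LoRAConfig(), seed=fed_cfg.seed + 1)
    state = GlobalState(model=model)
    for _ in range(fed_cfg.rounds):
        state = run_round(state, shards, fed_cfg, client_cfg, test_images, test_labels)
    return state


def convergence_rounds(
    history: list[RoundLog], target_metric: str, threshold: float
) -> Optional[int]:
    """First round whose metric reaches the threshold; None if never."""
    if not history:
        raise EmptyDataError("empty history")
    if target_metric not in ("accuracy",):
        raise ConfigurationError(f"unknown metric {target_metric!r}")
    for log in history:
        if getattr(log, target_metric) >= threshold:
            return log.round
    return None


def history_frame(state: GlobalState):
    """Round log as a DataFrame (round, accuracy, loss, payload bytes)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "round": [h.round for h in state.history],
            "accuracy": [h.accuracy for h in state.history],
            "mean_local_loss": [h.mean_local_loss for h in state.history],
            "uplink_bytes": [h.uplink_bytes for h in state.history],
            "downlink_bytes": [h.downlink_bytes for h in state.history],
        }
    )
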