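"""Low-rank adaptation (LoRA) of the attention query/value projections.

Instead of updating a frozen projection W0 (d x k) directly, LoRA learns
Delta W = A B with A (d x r), B (r x k) and r << min(d, k), applied as
W = W0 + s * A B.  Two scaling conventions are supported: the standard
s = alpha / r (default) and the literal s = alpha.  B starts at zero, so an
adapted model is exactly the base model until training moves B.

Adapters live in the same flat parameter dictionary as the backbone under
``blocks.{i}.attn.{query|value}.lora_A/lora_B``; injection freezes every base
tensor, which makes trainable-parameter accounting and federated payload
accounting exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import lora_scaling
from .errors import ConfigurationError, IncompatibilityError, ShapeError
from .vit import ModelState, ViTConfig

__all__ = [
    "LoRAConfig",
    "AdapterPair",
    "inject_lora",
    "lora_forward",
    "count_lora_parameters",
    "extract_adapter_state",
    "load_adapter_state",
    "merge_adapters",
    "save_adapter_state",
    "read_adapter_state",
]

_VALID_TARGETS = ("query", "value")


@dataclass(frozen=True)
class LoRAConfig:
    rank: int = 16
    alpha: float = 32.0
    dropout: float = 0.1
    target_modules: tuple[str, ...] = ("query", "value")
    scaling_convention: str = "alpha_over_r"
    train_head: bool = False

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ConfigurationError("LoRA rank must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.scaling_convention not in ("alpha_over_r", "alpha_literal"):
            raise ConfigurationError(
                f"unknown scaling convention {self.scaling_convention!r}"
            )
        for t in self.target_modules:
            if t not in _VALID_TARGETS:
                raise ConfigurationError(
                    f"unknown target module {t!r}; supported: {_VALID_TARGETS}"
                )

    @property
    def scaling(self) -> float:
        return lora_scaling(self)


@dataclass
class AdapterPair:
    """The low-rank factors of one adapted projection."""

    A: np.ndarray  # (d, r)
    B: np.ndarray  # (r, k)
    owner: tuple[int, str]  # (block index, projection name)

    @property
    def delta(self) -> np.ndarray:
        return self.A @ self.B


def inject_lora(model: ModelState, cfg: LoRAConfig, seed: int) -> ModelState:
    """Attach adapters to the configured projections and freeze the base.

    A is initialized Gaussian (sigma = 1/r), B zero, so forward outputs are
    unchanged at injection time.  The classifier head stays trainable only if
    ``cfg.train_head`` is set.
    """
    d = model.config.embed_dim
    if cfg.rank >= d:
        raise ConfigurationError(f"rank {cfg.rank} must be < embed dim {d}")
    out = model.copy()
    rng = np.random.default_rng(seed)
    for k in out.trainable:
        out.trainable[k] = False
    for i in range(model.config.depth):
        for name in cfg.target_modules:
            a_key = f"blocks.{i}.attn.{name}.lora_A"
            b_key = f"blocks.{i}.attn.{name}.lora_B"
            out.params[a_key] = rng.normal(0.0, 1.0 / cfg.rank, (d, cfg.rank)).astype(
                np.float32
            )
            out.params[b_key] = np.zeros((cfg.rank, d), dtype=np.float32)
            out.trainable[a_key] = True
            out.trainable[b_key] = True
    if cfg.train_head:
        out.trainable["head.weight"] = True
        out.trainable["head.bias"] = True
    out.lora = cfg
    return out


def lora_forward(
    x: np.ndarray,
    W0: np.ndarray,
    pair: AdapterPair,
    cfg: LoRAConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """x (W0 + s A B), with dropout on the adapter path only (training mode)."""
    x = np.asarray(x)
    if x.shape[-1] != W0.shape[0] or pair.A.shape[0] != W0.shape[0] or pair.B.shape[1] != W0.shape[1]:
        raise ShapeError(
            f"incompatible shapes x{x.shape}, W0{W0.shape}, A{pair.A.shape}, B{pair.B.shape}"
        )
    xa = x
    if train and cfg.dropout > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        xa = x * ((rng.random(x.shape) >= cfg.dropout) / (1.0 - cfg.dropout))
    return x @ W0 + cfg.scaling * ((xa @ pair.A) @ pair.B)


def count_lora_parameters(vit: ViTConfig, cfg: LoRAConfig) -> int:
    """L * |targets| * (d r + r k); query/value keep k = d."""
    d = vit.embed_dim
    return vit.depth * len(cfg.target_modules) * (d * cfg.rank + cfg.rank * d)


def adapter_keys(model: ModelState) -> list[str]:
    return sorted(k for k in model.params if ".lora_" in k)


def extract_adapter_state(model: ModelState) -> dict[str, np.ndarray]:
    """The transmissible update: A/B tensors (plus head when trained)."""
    if model.lora is None:
        raise IncompatibilityError("model has no adapters")
    state = {k: model.params[k].copy() for k in adapter_keys(model)}
    if model.lora.train_head:
        state["head.weight"] = model.params["head.weight"].copy()
        state["head.bias"] = model.params["head.bias"].copy()
    return state


def load_adapter_state(model: ModelState, state: dict[str, np.ndarray]) -> ModelState:
    expected = set(extract_adapter_state(model))
    if set(state) != expected:
        raise IncompatibilityError(
            f"adapter state keys do not match model: {sorted(set(state) ^ expected)}"
        )
    for k, v in state.items():
        if model.params[k].shape != v.shape:
            raise IncompatibilityError(f"shape mismatch for {k}")
        model.params[k] = np.asarray(v).copy()
    return model


def get_adapter_pair(model: ModelState, block: int, name: str) -> AdapterPair:
    return AdapterPair(
        A=model.params[f"blocks.{block}.attn.{name}.lora_A"],
        B=model.params[f"blocks.{block}.attn.{name}.lora_B"],
        owner=(block, name),
    )


def merge_adapters(model: ModelState) -> ModelState:
    """Fold s*A*B into the fused QKV weights and drop the adapters.

    The merged model has no LoRA tensors and reproduces the adapted model's
    eval-mode outputs (up to float roundoff).  Merging an adapter-free model
    is a no-op, so merging twice is idempotent.
    """
    if model.lora is None:
        return model.copy()
    cfg = model.lora
    out = model.copy()
    d = model.config.embed_dim
    offsets = {"query": 0, "value": 2 * d}
    for i in range(model.config.depth):
        for name in cfg.target_modules:
            a_key = f"blocks.{i}.attn.{name}.lora_A"
            if a_key not in out.params:
                continue
            pair = get_adapter_pair(out, i, name)
            W = out.params[f"blocks.{i}.attn.qkv.weight"]
            off = offsets[name]
            W[:, off : off + d] += (cfg.scaling * pair.delta).astype(W.dtype)
            for key in (a_key, f"blocks.{i}.attn.{name}.lora_B"):
                del out.params[key]
                del out.trainable[key]
    out.lora = None
    return out


def save_adapter_state(model: ModelState, path: str) -> None:
    """Portable adapter file: one array per tensor + JSON header (r, alpha, convention)."""
    import h5py

    cfg = model.lora
    if cfg is None:
        raise IncompatibilityError("model has no adapters")
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(
            {
                "rank": cfg.rank,
                "alpha": cfg.alpha,
                "scaling_convention": cfg.scaling_convention,
                "train_head": cfg.train_head,
            }
        )
        for k, v in extract_adapter_state(model).items():
            f.create_dataset(k, data=v)


def read_adapter_state(path: str) -> tuple[dict, dict[str, np.ndarray]]:
    import h5py

    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        state = {k: np.asarray(f[k]) for k in f.keys()}
    return header, state
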