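"""DeiT-tiny Vision Transformer backbone in NumPy.

The model is stored as a flat ``{name: ndarray}`` parameter dictionary plus a
per-tensor trainable mask, which keeps federated weight exchange, LoRA
injection and parameter accounting exact and transparent.  The architecture
is the standard DeiT-tiny: 16x16 patch embedding, a learnable CLS token,
learnable positional embeddings, 12 pre-norm encoder blocks (3-head MHSA,
GELU MLP with ratio 4), a final layer norm and a linear head read off the
CLS token.  No distillation token is used: with a 2-class head this is the
variant whose parameter counts match the published accounting exactly.

Patch flattening is row-major over the patch grid and, within a patch,
row-major by pixel then channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigurationError, IncompatibilityError, ShapeError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .lora import LoRAConfig

__all__ = [
    "ViTConfig",
    "ModelState",
    "build_model",
    "embed_patches",
    "encoder_block",
    "forward_logits",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ViTConfig:
    """Architecture hyperparameters of the classifier backbone."""

    image_size: int = 224
    patch_size: int = 16
    in_channels: int = 3
    embed_dim: int = 192
    depth: int = 12
    num_heads: int = 3
    mlp_ratio: int = 4
    num_classes: int = 2
    use_distillation_token: bool = False

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if self.embed_dim % self.num_heads != 0:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}"
            )
        if self.use_distillation_token:
            raise ConfigurationError("distillation token is not supported")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size**2

    @property
    def seq_len(self) -> int:
        return self.num_patches + 1  # CLS prepended

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * self.in_channels

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads

    @property
    def mlp_hidden(self) -> int:
        return self.embed_dim * self.mlp_ratio


@dataclass
class ModelState:
    """Full weight set of the classifier plus per-tensor trainable flags."""

    config: ViTConfig
    params: dict[str, np.ndarray]
    trainable: dict[str, bool]
    lora: Optional["LoRAConfig"] = None

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            trainable=dict(self.trainable),
            lora=self.lora,
        )

    def trainable_keys(self) -> list[str]:
        return [k for k, v in self.trainable.items() if v]


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    # truncated at +-2 sigma, the DeiT convention
    x = truncnorm.rvs(-2.0, 2.0, scale=std, size=int(np.prod(shape)), random_state=rng)
    return np.asarray(x, dtype=np.float32).reshape(shape)


def block_param_names(i: int) -> list[str]:
    p = f"blocks.{i}"
    return [
        f"{p}.ln1.weight",
        f"{p}.ln1.bias",
        f"{p}.attn.qkv.weight",
        f"{p}.attn.qkv.bias",
        f"{p}.attn.proj.weight",
        f"{p}.attn.proj.bias",
        f"{p}.ln2.weight",
        f"{p}.ln2.bias",
        f"{p}.mlp.fc1.weight",
        f"{p}.mlp.fc1.bias",
        f"{p}.mlp.fc2.weight",
        f"{p}.mlp.fc2.bias",
    ]


def build_model(
    config: ViTConfig, seed: int, checkpoint: str | None = None
) -> ModelState:
    """Initialize a full model; deterministic for a fixed seed.

    Projection weights are truncated-normal (sigma 0.02), biases zero, layer
    norms identity.  When ``checkpoint`` is given, weights are loaded from it
    instead (see :func:`load_checkpoint`).
    """
    if checkpoint is not None:
        return load_checkpoint(checkpoint)
    rng = np.random.default_rng(seed)
    d = config.embed_dim
    params: dict[str, np.ndarray] = {}
    params["patch_embed.weight"] = _trunc_normal(rng, (config.patch_dim, d))
    params["patch_embed.bias"] = np.zeros(d, dtype=np.float32)
    params["cls_token"] = _trunc_normal(rng, (d,))
    params["pos_embed"] = _trunc_normal(rng, (config.seq_len, d))
    for i in range(config.depth):
        p = f"blocks.{i}"
        params[f"{p}.ln1.weight"] = np.ones(d, dtype=np.float32)
        params[f"{p}.ln1.bias"] = np.zeros(d, dtype=np.float32)
        params[f"{p}.attn.qkv.weight"] = _trunc_normal(rng, (d, 3 * d))
        params[f"{p}.attn.qkv.bias"] = np.zeros(3 * d, dtype=np.float32)
        params[f"{p}.attn.proj.weight"] = _trunc_normal(rng, (d, d))
        params[f"{p}.attn.proj.bias"] = np.zeros(d, dtype=np.float32)
        params[f"{p}.ln2.weight"] = np.ones(d, dtype=np.float32)
        params[f"{p}.ln2.bias"] = np.zeros(d, dtype=np.float32)
        params[f"{p}.mlp.fc1.weight"] = _trunc_normal(rng, (d, config.mlp_hidden))
        params[f"{p}.mlp.fc1.bias"] = np.zeros(config.mlp_hidden, dtype=np.float32)
        params[f"{p}.mlp.fc2.weight"] = _trunc_normal(rng, (config.mlp_hidden, d))
        params[f"{p}.mlp.fc2.bias"] = np.zeros(d, dtype=np.float32)
    params["norm.weight"] = np.ones(d, dtype=np.float32)
    params["norm.bias"] = np.zeros(d, dtype=np.float32)
    params["head.weight"] = _trunc_normal(rng, (d, config.num_classes))
    params["head.bias"] = np.zeros(config.num_classes, dtype=np.float32)
    trainable = {k: True for k in params}
    return ModelState(config=config, params=params, trainable=trainable)


def patchify(images: np.ndarray, config: ViTConfig) -> np.ndarray:
    """(B, H, W, C) -> (B, num_patches, patch_dim), row-major patch order."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    B, H, W, C = images.shape
    if H != config.image_size or W != config.image_size or C != config.in_channels:
        raise ShapeError(
            f"expected {config.image_size}x{config.image_size}x{config.in_channels}, "
            f"got {H}x{W}x{C}"
        )
    P, g = config.patch_size, config.grid_size
    x = images.reshape(B, g, P, g, P, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)  # (B, gy, gx, P, P, C)
    return x.reshape(B, config.num_patches, config.patch_dim)


def embed_patches(image: np.ndarray, model: ModelState) -> np.ndarray:
    """Token sequence Z0 = [x_cls; x_p^i E ...] + E_pos, shape (B, N+1, d)."""
    cfg = model.config
    x = patchify(image, cfg)
    z = x @ model.params["patch_embed.weight"] + model.params["patch_embed.bias"]
    cls = np.broadcast_to(model.params["cls_token"], (z.shape[0], 1, cfg.embed_dim))
    z = np.concatenate([cls, z], axis=1)
    return z + model.params["pos_embed"]


def encoder_block(
    tokens: np.ndarray,
    model: ModelState,
    block_index: int,
    return_attention: bool = False,
):
    """Apply one pre-norm encoder block (eval mode).

    ``tokens`` is (B, T, d) or (T, d); LoRA adapters attached to this block's
    query/value projections are applied automatically.
    """
    from . import autodiff

    squeeze = tokens.ndim == 2
    x = tokens[None] if squeeze else tokens
    if x.shape[-1] != model.config.embed_dim:
        raise ShapeError(f"token dim {x.shape[-1]} != embed dim {model.config.embed_dim}")
    out, cache = autodiff.block_forward(
        x, model.params, block_index, model.config, model.lora, train=False, rng=None
    )
    out = out[0] if squeeze else out
    if return_attention:
        return out, cache["attn_weights"]
    return out


def forward_logits(images: np.ndarray, model: ModelState) -> np.ndarray:
    """Class scores (B, num_classes) in eval mode (dropout disabled)."""
    from . import autodiff

    logits, _ = autodiff.model_forward(model, images, train=False, rng=None)
    return logits


def count_parameters(model: ModelState, trainable_only: bool = False) -> int:
    """Exact element count of the weight set (optionally trainable tensors only)."""
    return sum(
        v.size
        for k, v in model.params.items()
        if not trainable_only or model.trainable[k]
    )


def save_checkpoint(model: ModelState, path: str) -> None:
    """Write all tensors plus a JSON metadata block (config, mask, LoRA config)."""
    import h5py

    from .lora import LoRAConfig  # noqa: F401 - for round trip

    meta = {
        "config": model.config.__dict__,
        "trainable": model.trainable,
        "lora": None
        if model.lora is None
        else {
            "rank": model.lora.rank,
            "alpha": model.lora.alpha,
            "dropout": model.lora.dropout,
            "target_modules": list(model.lora.target_modules),
            "scaling_convention": model.lora.scaling_convention,
            "train_head": model.lora.train_head,
        },
    }
    with h5py.File(path, "w") as f:
        f.attrs["metadata"] = json.dumps(meta)
        for k, v in model.params.items():
            f.create_dataset(k, data=v)


def load_checkpoint(path: str) -> ModelState:
    import h5py

    from .lora import LoRAConfig

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        params = {k: np.asarray(f[k]) for k in f.keys()}
    cfg = ViTConfig(**meta["config"])
    lora = None if meta["lora"] is None else LoRAConfig(**meta["lora"])
    model = ModelState(
        config=cfg, params=params, trainable=dict(meta["trainable"]), lora=lora
    )
    missing = set(model.trainable) ^ set(params)
    if missing:
        raise IncompatibilityError(f"checkpoint/mask key mismatch: {sorted(missing)}")
    return model


def base_parameter_count(config: ViTConfig) -> int:
    """Closed-form parameter count of the adapter-free model."""
    d, N, L = config.embed_dim, config.num_patches, config.depth
    h = config.mlp_hidden
    per_block = 2 * 2 * d + (d * 3 * d + 3 * d) + (d * d + d) + (d * h + h) + (h * d + d)
    return (
        (config.patch_dim * d + d)  # patch projection
        + d  # CLS token
        + (N + 1) * d  # positional embedding
        + L * per_block
        + 2 * d  # final layer norm
        + (d * config.num_classes + config.num_classes)  # head
    )
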