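"""The packaged synthetic non-IID benchmark.

LoRA fine-tuning presumes a pretrained backbone, so the benchmark mirrors
the full pipeline at desk scale in two stages:

1. *Pretraining*: the tiny backbone (image 64, patch 16, embed 48, depth 4)
   is trained centrally on a synthetic source domain with a weaker class
   effect and heavier noise — a stand-in for generic pretraining.
2. *Federated adaptation*: the target-domain training set is split across
   10 clients with Dirichlet(0.3) label skew plus a per-client intensity
   shift (hospital-specific scanners), and each strategy arm — fedavg,
   fedavg_lora, fedprox, fedprox_lora — adapts the shared pretrained model
   over 10 communication rounds.  LoRA arms train rank-16 adapters and the
   classification head; full arms train everything.  FedProx arms use
   mu = 0.5.  Clients fine-tune with AdamW at 1e-4 (2 local epochs,
   batch 8), the published fine-tuning setting.

All sampling is keyed to one integer seed, so a run is reproducible
end to end.
"""

from __future__ import annotations

import numpy as np

from .client import FedProxConfig, local_train
from .data import ClientShard, SyntheticConfig, generate_synthetic_cxr, partition_noniid
from .lora import LoRAConfig, inject_lora
from .server import FederationConfig, GlobalState, run_federated_training
from .vit import ModelState, ViTConfig, build_model

__all__ = ["BENCH_VIT", "BENCH_LORA", "pretrain_backbone", "make_benchmark_data", "run_benchmark"]

BENCH_VIT = ViTConfig(image_size=64, patch_size=16, embed_dim=48, depth=4, num_heads=3)
BENCH_LORA = LoRAConfig(rank=16, alpha=32, dropout=0.1, train_head=True)


def _images(ds):
    return np.stack([ds.image(i) for i in range(len(ds))])


def pretrain_backbone(
    vit_cfg: ViTConfig = BENCH_VIT,
    seed: int = 0,
    n_images: int = 300,
    effect_size: float = 0.15,
    noise_sd: float = 0.08,
    epochs: int = 6,
    learning_rate: float = 1e-3,
    batch_size: int = 16,
) -> ModelState:
    """Centralized source-domain training that stands in for pretraining."""
    ds = generate_synthetic_cxr(
        SyntheticConfig(
            n_images=n_images,
            image_size=vit_cfg.image_size,
            effect_size=effect_size,
            noise_sd=noise_sd,
            seed=seed,
        )
    )
    model = build_model(vit_cfg, seed=seed)
    update = local_train(
        ClientShard(0, _images(ds), ds.labels),
        model,
        FedProxConfig(
            mu=0.0,
            local_epochs=epochs,
            batch_size=batch_size,
            learning_rate=learning_rate,
            seed=seed,
        ),
    )
    for k, v in update.weights.items():
        model.params[k] = v
    return model


def make_benchmark_data(
    seed: int = 0,
    n_train: int = 400,
    n_test: int = 200,
    n_clients: int = 10,
    beta: float = 0.3,
    client_shift: float = 0.08,
    effect_size: float = 0.25,
    noise_sd: float = 0.05,
    image_size: int = 64,
):
    """Target-domain train shards and held-out test set (images, labels)."""
    train = generate_synthetic_cxr(
        SyntheticConfig(n_images=n_train, image_size=image_size, effect_size=effect_size, noise_sd=noise_sd, seed=seed)
    )
    test = generate_synthetic_cxr(
        SyntheticConfig(n_images=n_test, image_size=image_size, effect_size=effect_size, noise_sd=noise_sd, seed=seed + 1)
    )
    shards = partition_noniid(
        _images(train), train.labels, K=n_clients, beta=beta, seed=seed, client_shift=client_shift
    )
    return shards, _images(test), test.labels


def run_benchmark(
    strategies=("fedavg", "fedavg_lora", "fedprox", "fedprox_lora"),
    seed: int = 0,
    rounds: int = 10,
    n_clients: int = 10,
    mu: float = 0.5,
    local_epochs: int = 2,
    learning_rate: float = 1e-4,
    batch_size: int = 8,
) -> dict[str, GlobalState]:
    """Run the requested strategy arms from one shared pretrained backbone."""
    pre = pretrain_backbone(BENCH_VIT, seed=seed + 1000)
    shards, test_images, test_labels = make_benchmark_data(seed=seed, n_clients=n_clients)
    out: dict[str, GlobalState] = {}
    for strategy in strategies:
        fed_cfg = FederationConfig(
            n_clients=n_clients, rounds=rounds, strategy=strategy, mu=mu, seed=seed
        )
        init = pre.copy()
        if fed_cfg.uses_lora:
            init = inject_lora(init, BENCH_LORA, seed=seed + 1)
        out[strategy] = run_federated_training(
            fed_cfg,
            shards,
            test_images,
            test_labels,
            BENCH_VIT,
            lora_cfg=BENCH_LORA,
            client_cfg=FedProxConfig(
                mu=fed_cfg.effective_mu,
                local_epochs=local_epochs,
                batch_size=batch_size,
                learning_rate=learning_rate,
                seed=seed,
            ),
            initial_model=init,
        )
    return out
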