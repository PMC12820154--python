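import numpy as np
import pytest

from fedlora import LoRAConfig, ViTConfig, build_model, inject_lora


@pytest.fixture(scope="session")
def tiny_cfg() -> ViTConfig:
    """A 5-token, 8-dim model small enough for brute-force oracles."""
    return ViTConfig(
        image_size=16, patch_size=8, in_channels=3, embed_dim=8, depth=2, num_heads=2
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg, seed=0)


@pytest.fixture(scope="session")
def deit_tiny_cfg() -> ViTConfig:
    return ViTConfig()  # full DeiT-tiny defaults: 224/16/192/12/3 heads


@pytest.fixture(scope="session")
def deit_tiny(deit_tiny_cfg):
    return build_model(deit_tiny_cfg, seed=0)


@pytest.fixture(scope="session")
def deit_tiny_lora(deit_tiny):
    return inject_lora(deit_tiny, LoRAConfig(), seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
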