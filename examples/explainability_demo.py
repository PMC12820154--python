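"""Attention-rollout and RISE heatmaps on a synthetic pneumonia image.

Trains nothing: uses a freshly initialized tiny backbone for the rollout
(the mechanics are weight-agnostic) and a transparent intensity scorer for
RISE, then reports how much of the top-decile saliency falls inside the
lung fields where the opacity blobs were planted.
"""

from pathlib import Path

import numpy as np

from fedlora import (
    SyntheticConfig,
    ViTConfig,
    attention_rollout,
    build_model,
    generate_synthetic_cxr,
    lung_field_mask,
    overlay,
    rise_saliency,
)

size = 64
ds = generate_synthetic_cxr(
    SyntheticConfig(n_images=20, effect_size=0.5, noise_sd=0.05, image_size=size, seed=0)
)
idx = int(np.flatnonzero(ds.labels == 1)[0])
img = ds.image(idx)
mask = lung_field_mask(size)

model = build_model(ViTConfig(image_size=size, patch_size=16, embed_dim=48, depth=4, num_heads=3), seed=0)
rollout = attention_rollout(model, img)
print(f"attention rollout: {rollout.grid.shape} heatmap, max {rollout.grid.max():.2f}")


def scorer(batch):  # mean in-lung brightness as a pneumonia score
    return batch[:, mask].mean(axis=1)


rise = rise_saliency(scorer, img, n_masks=1500, cell_grid=8, seed=2)
top = rise.grid >= np.quantile(rise.grid, 0.9)
inside = top[mask].sum() / top.sum()
print(f"RISE: {inside:.0%} of top-decile saliency falls inside the lung fields "
      f"(lung area is {mask.mean():.0%} of the image)")

out = Path("scratch")
out.mkdir(exist_ok=True)
overlay(img, rise, alpha=0.5, out_path=str(out / "rise_overlay.png"))
overlay(img, rollout, alpha=0.5, out_path=str(out / "rollout_overlay.png"))
print(f"overlays written to {out}/")
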