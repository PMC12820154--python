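"""Explainability: attention rollout for the CLS token and RISE saliency.

Attention rollout multiplies the per-block, head-averaged attention matrices
(each mixed 50/50 with the identity to account for residual connections and
re-row-normalized) and reads off the CLS row over patch tokens.  RISE probes
the model as a black box: random binary cell grids are upsampled to soft
occlusion masks and the saliency map is the score-weighted mean of the
masks, normalized by per-pixel mask coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import autodiff
from .data import preprocess_batch
from .errors import ShapeError
from .vit import ModelState

__all__ = ["Heatmap", "attention_rollout", "rise_saliency", "overlay"]


@dataclass
class Heatmap:
    grid: np.ndarray  # (H, W), values in [0, 1] after normalization
    source: str  # "rollout" | "rise"


def _normalize(h: np.ndarray) -> np.ndarray:
    h = h - h.min()
    m = h.max()
    return h / m if m > 0 else h


def rollout_matrix(attentions: list[np.ndarray], head_agg: str = "mean") -> np.ndarray:
    """Multiply identity-mixed, head-aggregated attentions across blocks.

    ``attentions`` holds per-block arrays (H, T, T); returns (T, T).
    """
    agg = {"mean": np.mean, "max": np.max}[head_agg]
    T = attentions[0].shape[-1]
    rollout = np.eye(T)
    for a in attentions:
        mixed = 0.5 * agg(a, axis=0) + 0.5 * np.eye(T)
        mixed = mixed / mixed.sum(axis=-1, keepdims=True)
        rollout = mixed @ rollout
    return rollout


def attention_rollout(
    model: ModelState, image: np.ndarray, head_agg: str = "mean"
) -> Heatmap:
    """CLS-to-patch attribution upsampled to the input resolution."""
    cfg = model.config
    x = preprocess_batch(image[None] if image.ndim == 2 else image)
    if x.ndim == 3:
        x = x[None]
    _, aux = autodiff.model_forward(model, x, train=False)
    attns = [a[0] for a in aux["attn"]]  # (H, T, T) per block
    rollout = rollout_matrix(attns, head_agg)
    cls_row = rollout[0, 1:]  # attribution of CLS onto patch tokens
    g = cfg.grid_size
    patch_map = cls_row.reshape(g, g)
    grid = resize(patch_map, (cfg.image_size, cfg.image_size), order=1, mode="edge")
    return Heatmap(grid=_normalize(grid), source="rollout")


def _default_scorer(model: ModelState):
    """Probability of the class the model predicts on the unmasked image."""
    target = {"cls": None}

    def scorer(batch_gray: np.ndarray) -> np.ndarray:
        x = preprocess_batch(batch_gray)
        logits, _ = autodiff.model_forward(model, x, train=False)
        p = autodiff.softmax(logits, axis=-1)
        if target["cls"] is None:
            target["cls"] = int(logits[0].argmax())
        return p[:, target["cls"]]

    return scorer


def rise_saliency(
    model,
    image: np.ndarray,
    n_masks: int = 1000,
    cell_grid: int = 7,
    keep_prob: float = 0.5,
    seed: int = 0,
    batch_size: int = 64,
    coverage_correction: bool = True,
    normalize: bool = True,
) -> Heatmap:
    """Randomized-mask saliency for the predicted class.

    ``model`` may be a ModelState or any callable mapping a grayscale batch
    (n, H, W) to scores (n,).  Masks are Bernoulli(keep_prob) cell grids,
    bilinearly upsampled with a random sub-cell offset.  With coverage
    correction the per-pixel weighted score sum is divided by the per-pixel
    mask sum (exactly constant for a constant scorer); otherwise by
    n_masks * keep_prob.
    """
    if n_masks < 1:
        raise ValueError("n_masks must be >= 1")
    image = np.asarray(image, dtype=np.float32)
    H, W = image.shape[-2:]
    rng = np.random.default_rng(seed)
    scorer = _default_scorer(model) if isinstance(model, ModelState) else model
    # score the unmasked image first so the target class is fixed
    scorer(image[None])
    ch, cw = int(np.ceil(H / cell_grid)), int(np.ceil(W / cell_grid))
    acc = np.zeros((H, W), dtype=np.float64)
    cov = np.zeros((H, W), dtype=np.float64)
    for start in range(0, n_masks, batch_size):
        nb = min(batch_size, n_masks - start)
        masks = np.empty((nb, H, W), dtype=np.float32)
        for i in range(nb):
            cells = (rng.random((cell_grid, cell_grid)) < keep_prob).astype(np.float32)
            up = resize(
                cells,
                ((cell_grid + 1) * ch, (cell_grid + 1) * cw),
                order=1,
                mode="edge",
            )
            oy, ox = rng.integers(0, ch + 1), rng.integers(0, cw + 1)
            masks[i] = up[oy : oy + H, ox : ox + W]
        scores = np.asarray(scorer(masks * image), dtype=np.float64)
        acc += np.tensordot(scores, masks, axes=(0, 0))
        cov += masks.sum(axis=0)
    if coverage_correction:
        sal = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    else:
        sal = acc / (n_masks * keep_prob)
    return Heatmap(grid=_normalize(sal) if normalize else sal, source="rise")


def overlay(
    image: np.ndarray,
    heatmap: Heatmap,
    alpha: float = 0.5,
    cmap: str = "jet",
    out_path: str | None = None,
) -> np.ndarray:
    """Alpha-blend a color-mapped heatmap over a grayscale image -> uint8 RGB."""
    import matplotlib

    image = np.asarray(image, dtype=np.float64)
    if image.shape != heatmap.grid.shape:
        raise ShapeError(
            f"image {image.shape} and heatmap {heatmap.grid.shape} sizes differ"
        )
    colors = matplotlib.colormaps[cmap](heatmap.grid)[..., :3]
    base = np.repeat(np.clip(image, 0, 1)[..., None], 3, axis=-1)
    blended = (1 - alpha) * base + alpha * colors
    out = np.rint(np.clip(blended, 0, 1) * 255).astype(np.uint8)
    if out_path is not None:
        from PIL import Image as PILImage

        PILImage.fromarray(out).save(out_path)
    return out
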