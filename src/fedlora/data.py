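"""Dataset handling: image-folder I/O, preprocessing, split redistribution,
Dirichlet non-IID client partitioning, a synthetic chest-X-ray generator, and
a t-SNE-based heterogeneity score.

The synthetic generator emulates the gross structure of a frontal chest
radiograph at small resolution: a dark background, two bright elliptical lung
fields, and — for the pneumonia class — additive Gaussian "opacity" blobs
planted inside the lung fields, on top of pixel noise.  It exists so the full
federated pipeline (partitioning, local training, aggregation, evaluation,
explainability) can run end to end without any external download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageEnhance

from .errors import ConfigurationError, EmptyDataError, LayoutError

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledImageSet",
    "ClientShard",
    "SyntheticConfig",
    "load_image_folder",
    "preprocess",
    "preprocess_batch",
    "redistribute_splits",
    "partition_noniid",
    "dirichlet_label_partition",
    "generate_synthetic_cxr",
    "lung_field_mask",
    "heterogeneity_score",
    "write_partition_manifest",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

LABEL_NAMES = {0: "NORMAL", 1: "PNEUMONIA"}
_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}


@dataclass
class LabeledImageSet:
    """Images (in memory or on disk) with binary labels; 0 normal, 1 pneumonia."""

    items: list  # (source, label); source is a Path or an ndarray in [0, 1]
    split: str = ""

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.items], dtype=np.int64)

    def image(self, i: int) -> np.ndarray:
        src, _ = self.items[i]
        if isinstance(src, np.ndarray):
            return src
        with Image.open(src) as im:
            return np.asarray(im.convert("L"), dtype=np.float32) / 255.0


@dataclass
class ClientShard:
    """One client's local dataset."""

    client_id: int
    images: np.ndarray  # (n, H, W) grayscale in [0, 1]
    labels: np.ndarray  # (n,)

    @property
    def n_i(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SyntheticConfig:
    n_images: int = 600
    prevalence: float = 0.5
    image_size: int = 64
    effect_size: float = 0.25
    client_shift: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")


# ---------------------------------------------------------------------------
# folder I/O and preprocessing


def load_image_folder(root: str | Path) -> dict[str, LabeledImageSet]:
    """Enumerate a split/class image folder (train|val|test x NORMAL|PNEUMONIA).

    Class labels come from directory names; enumeration is lexicographic so
    repeated loads give identical orderings.
    """
    root = Path(root)
    if not root.is_dir():
        raise LayoutError(f"{root} is not a directory")
    out: dict[str, LabeledImageSet] = {}
    splits = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not splits:
        raise LayoutError(f"{root} has no split subdirectories")
    for split in splits:
        items = []
        class_dirs = sorted(p for p in (root / split).iterdir() if p.is_dir())
        if not class_dirs:
            raise LayoutError(f"{root / split} has no class subdirectories")
        for cdir in class_dirs:
            name = cdir.name.upper()
            label = 1 if name == "PNEUMONIA" else 0
            files = sorted(
                p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
            )
            if not files:
                logger.warning("empty class folder: %s", cdir)
            items.extend((p, label) for p in files)
        out[split] = LabeledImageSet(items=items, split=split)
    return out


def preprocess(
    image,
    size: int = 224,
    train: bool = False,
    rng: np.random.Generator | None = None,
    rotation_deg: float = 10.0,
    flip_prob: float = 0.5,
    jitter: float = 0.1,
) -> np.ndarray:
    """Resize, replicate gray to RGB and standardize with ImageNet statistics.

    Training mode additionally applies small random rotation, horizontal flip
    and brightness jitter.  Eval mode is deterministic.
    """
    if isinstance(image, (str, Path)):
        with Image.open(image) as im:
            pil = im.convert("L")
    else:
        arr = np.asarray(image)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        arr = np.clip(arr, 0.0, 1.0) if arr.dtype.kind == "f" else arr / 255.0
        pil = Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L")
    if train:
        if rng is None:
            rng = np.random.default_rng()
        if rotation_deg > 0:
            pil = pil.rotate(float(rng.uniform(-rotation_deg, rotation_deg)), resample=Image.BILINEAR)
        if rng.random() < flip_prob:
            pil = pil.transpose(Image.FLIP_LEFT_RIGHT)
        if jitter > 0:
            pil = ImageEnhance.Brightness(pil).enhance(1.0 + float(rng.uniform(-jitter, jitter)))
    pil = pil.resize((size, size), resample=Image.BILINEAR)
    gray = np.asarray(pil, dtype=np.float32) / 255.0
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    return (rgb - IMAGENET_MEAN) / IMAGENET_STD


def preprocess_batch(gray: np.ndarray) -> np.ndarray:
    """Vectorized channel replication + standardization for already-sized
    grayscale batches (n, H, W) in [0, 1]; no resizing or augmentation."""
    rgb = np.repeat(np.asarray(gray, dtype=np.float32)[..., None], 3, axis=-1)
    return (rgb - IMAGENET_MEAN) / IMAGENET_STD


# ---------------------------------------------------------------------------
# split redistribution and partitioning


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` with quotas' proportions."""
    floors = np.floor(quotas).astype(int)
    rem = total - floors.sum()
    if rem > 0:
        order = np.argsort(-(quotas - floors), kind="stable")
        floors[order[:rem]] += 1
    return floors


def redistribute_splits(train, val, test, val_fraction: float = 0.15, seed: int = 0):
    """Pool train+val and redraw a stratified validation split.

    ``round(val_fraction * |pool|)`` items go to the new validation set
    (allocated across classes by largest remainder), the rest to training;
    the test set is untouched.  Inputs are sequences of (item, label) pairs.
    """
    if not 0.0 < val_fraction < 1.0:
        raise ConfigurationError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pool = list(train) + list(val)
    n_val = int(round(val_fraction * len(pool)))
    labels = np.array([lab for _, lab in pool])
    classes = np.unique(labels)
    quotas = np.array([n_val * (labels == c).mean() for c in classes])
    alloc = _largest_remainder(quotas, n_val)
    val_idx: list[int] = []
    for c, k in zip(classes, alloc):
        idx = np.flatnonzero(labels == c)
        val_idx.extend(rng.permutation(idx)[:k].tolist())
    val_mask = np.zeros(len(pool), dtype=bool)
    val_mask[val_idx] = True
    new_train = [pool[i] for i in np.flatnonzero(~val_mask)]
    new_val = [pool[i] for i in np.flatnonzero(val_mask)]
    return new_train, new_val, list(test)


def dirichlet_label_partition(
    labels: np.ndarray, K: int, beta: float, seed: int, max_retries: int = 100
) -> list[np.ndarray]:
    """Label-skew partition: per class, client proportions ~ Dirichlet(beta).

    Returns K disjoint, exhaustive index arrays; resamples (bounded) until
    every client is non-empty.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if K < 1 or K > n:
        raise ConfigurationError(f"cannot split {n} items across {K} clients")
    if beta <= 0:
        raise ConfigurationError("beta must be > 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        parts: list[list[int]] = [[] for _ in range(K)]
        for c in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == c))
            props = rng.dirichlet(np.full(K, beta))
            counts = _largest_remainder(props * len(idx), len(idx))
            stops = np.cumsum(counts)[:-1]
            for k, chunk in enumerate(np.split(idx, stops)):
                parts[k].extend(chunk.tolist())
        if all(parts):
            return [np.sort(np.array(p, dtype=int)) for p in parts]
    raise ConfigurationError(
        f"could not produce {K} non-empty shards after {max_retries} attempts"
    )


def partition_noniid(
    images: np.ndarray,
    labels: np.ndarray,
    K: int = 10,
    beta: float = 0.5,
    seed: int = 0,
    client_shift: float = 0.0,
) -> list[ClientShard]:
    """Dirichlet label-skew partition into K client shards.

    ``client_shift`` adds a per-client global intensity offset (feature skew)
    drawn once per client.
    """
    parts = dirichlet_label_partition(labels, K, beta, seed)
    rng = np.random.default_rng(seed + 1)
    offsets = rng.normal(0.0, client_shift, K) if client_shift > 0 else np.zeros(K)
    shards = []
    for k, idx in enumerate(parts):
        imgs = np.asarray(images)[idx]
        if offsets[k] != 0.0:
            imgs = np.clip(imgs + offsets[k], 0.0, 1.0)
        shards.append(ClientShard(client_id=k, images=imgs, labels=np.asarray(labels)[idx]))
    return shards


def write_partition_manifest(shards: list[ClientShard], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for s in shards:
        for j, lab in enumerate(s.labels):
            rows.append({"item": f"client{s.client_id}/{j}", "label": int(lab), "client_id": s.client_id})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# synthetic generator


def lung_field_mask(size: int) -> np.ndarray:
    """Boolean mask of the two elliptical lung fields at the given resolution."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size
    left = ((xx - 0.33) / 0.16) ** 2 + ((yy - 0.52) / 0.30) ** 2 <= 1.0
    right = ((xx - 0.67) / 0.16) ** 2 + ((yy - 0.52) / 0.30) ** 2 <= 1.0
    return left | right


def generate_synthetic_cxr(cfg: SyntheticConfig) -> LabeledImageSet:
    """Two-class grayscale image set with a controllable class effect.

    Every image is a dark background plus bright lung fields and pixel noise;
    pneumonia images additionally carry 2-4 Gaussian opacity blobs of
    amplitude ~ ``effect_size`` centred inside the lung fields.  Labels are a
    stratified draw: exactly round(n * prevalence) positives, order shuffled.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(cfg.seed)
    S = cfg.image_size
    mask = lung_field_mask(S)
    in_lung = np.argwhere(mask)
    n_pos = int(round(cfg.n_images * cfg.prevalence))
    labels = np.zeros(cfg.n_images, dtype=np.int64)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    sigma_blob = 0.08 * S
    images = np.empty((cfg.n_images, S, S), dtype=np.float32)
    for i in range(cfg.n_images):
        img = np.full((S, S), 0.10, dtype=np.float64)
        img[mask] = 0.55
        img = gaussian_filter(img, sigma=0.02 * S)  # soften lung borders
        if labels[i] == 1 and cfg.effect_size > 0:
            for _ in range(rng.integers(2, 5)):
                cy, cx = in_lung[rng.integers(len(in_lung))]
                amp = cfg.effect_size * (0.7 + 0.6 * rng.random())
                img += amp * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_blob**2)
                ) * mask
        img += rng.normal(0.0, cfg.noise_sd, (S, S))
        images[i] = np.clip(img, 0.0, 1.0)
    items = [(images[i], int(labels[i])) for i in range(cfg.n_images)]
    return LabeledImageSet(items=items, split="synthetic")


def export_image_folder(dataset: LabeledImageSet, root: str | Path, split: str = "train") -> None:
    """Write a LabeledImageSet to the split/class PNG folder layout."""
    root = Path(root)
    for lab, name in LABEL_NAMES.items():
        (root / split / name).mkdir(parents=True, exist_ok=True)
    for i, (src, lab) in enumerate(dataset.items):
        arr = dataset.image(i)
        img = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8), mode="L")
        img.save(root / split / LABEL_NAMES[lab] / f"img{i:05d}.png")


# ---------------------------------------------------------------------------
# heterogeneity


def heterogeneity_score(
    client_features: list[np.ndarray],
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
) -> float:
    """Mean pairwise distance between client centroids in a 2-D embedding.

    ``method='tsne'`` embeds the pooled features with t-SNE (fixed seed);
    ``method='identity'`` uses the first two feature dimensions unchanged,
    making the centroid arithmetic exactly testable.
    """
    if len(client_features) < 2:
        raise ConfigurationError("need features from at least 2 clients")
    feats = [np.atleast_2d(np.asarray(f, dtype=np.float64)) for f in client_features]
    if any(len(f) == 0 for f in feats):
        raise EmptyDataError("every client needs at least one feature vector")
    X = np.vstack(feats)
    if method == "identity":
        emb = X[:, :2]
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(perplexity, (len(X) - 1) / 3)
        emb = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(X)
    else:
        raise ConfigurationError(f"unknown embedding method {method!r}")
    centroids = []
    start = 0
    for f in feats:
        centroids.append(emb[start : start + len(f)].mean(axis=0))
        start += len(f)
    C = np.array(centroids)
    dists = [
        float(np.linalg.norm(C[i] - C[j]))
        for i in range(len(C))
        for j in range(i + 1, len(C))
    ]
    return float(np.mean(dists))
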