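"""Data handling: folder I/O, preprocessing, split redistribution,
Dirichlet partitioning, the synthetic generator and heterogeneity scoring."""

import numpy as np
import pytest
from PIL import Image

from fedlora import (
    SyntheticConfig,
    generate_synthetic_cxr,
    heterogeneity_score,
    load_image_folder,
    lung_field_mask,
    partition_noniid,
    preprocess,
    redistribute_splits,
    roc_auc,
)
from fedlora.data import dirichlet_label_partition, preprocess_batch
from fedlora.errors import ConfigurationError, LayoutError


def _table1_sets():
    """Label-only stand-ins with the published original split counts."""
    train = [("t", 0)] * 1341 + [("t", 1)] * 3875
    val = [("v", 0)] * 8 + [("v", 1)] * 8
    test = [("s", 0)] * 234 + [("s", 1)] * 390
    return train, val, test


class TestFolderIO:
    def test_labels_from_folder_names(self, tmp_path):
        for split in ("train", "test"):
            for cls, n in (("NORMAL", 3), ("PNEUMONIA", 2)):
                d = tmp_path / split / cls
                d.mkdir(parents=True)
                for i in range(n if split == "train" else 1):
                    Image.new("L", (8, 8), color=100).save(d / f"im{i}.png")
        sets = load_image_folder(tmp_path)
        assert len(sets["train"]) == 5
        assert sets["train"].labels.sum() == 2  # two pneumonia items

    def test_missing_layout_raises(self, tmp_path):
        with pytest.raises(LayoutError):
            load_image_folder(tmp_path / "nope")
        (tmp_path / "train").mkdir()
        with pytest.raises(LayoutError):
            load_image_folder(tmp_path)


class TestPreprocess:
    def test_constant_mean_channel_standardizes_to_zero(self):
        img = np.full((32, 32), 0.485, dtype=np.float32)
        out = preprocess(img, size=32)
        np.testing.assert_allclose(out[..., 0], 0.0, atol=6e-3)  # 8-bit quantization

    def test_output_contract_any_input_size(self, rng):
        out = preprocess(rng.random((50, 70)), size=224)
        assert out.shape == (224, 224, 3)

    def test_eval_mode_deterministic(self, rng):
        img = rng.random((40, 40))
        np.testing.assert_array_equal(preprocess(img, 32), preprocess(img, 32))

    def test_train_mode_augments(self, rng):
        img = rng.random((40, 40))
        a = preprocess(img, 32, train=True, rng=np.random.default_rng(0))
        b = preprocess(img, 32, train=True, rng=np.random.default_rng(1))
        assert not np.array_equal(a, b)

    def test_batch_standardization_matches_formula(self, rng):
        gray = rng.random((2, 8, 8)).astype(np.float32)
        out = preprocess_batch(gray)
        np.testing.assert_allclose(out[..., 1], (gray - 0.456) / 0.224, rtol=1e-5)


class TestRedistribution:
    def test_published_resplit_counts(self):
        # pooled 5216 + 16 = 5232; 15% -> 785 validation, 4447 train; test 624
        train, val, test = redistribute_splits(*_table1_sets(), val_fraction=0.15, seed=0)
        assert (len(train), len(val), len(test)) == (4447, 785, 624)
        assert len(train) + len(val) + len(test) == 5856

    def test_tiny_fraction_sends_all_to_train(self):
        train, val, _ = redistribute_splits(
            [("a", 0)] * 6, [("b", 1)] * 1, [], val_fraction=0.05, seed=0
        )
        assert len(val) == 0 and len(train) == 7

    def test_conservation_for_random_inputs(self, rng):
        for _ in range(5):
            n1, n2, n3 = rng.integers(5, 50, 3)
            tr = [("x", int(l)) for l in rng.integers(0, 2, n1)]
            va = [("y", int(l)) for l in rng.integers(0, 2, n2)]
            te = [("z", int(l)) for l in rng.integers(0, 2, n3)]
            a, b, c = redistribute_splits(tr, va, te, val_fraction=0.2, seed=1)
            assert len(a) + len(b) == n1 + n2
            assert len(c) == n3

    def test_invalid_fraction(self):
        with pytest.raises(ConfigurationError):
            redistribute_splits([("a", 0)], [], [], val_fraction=1.5)


class TestDirichletPartition:
    def test_partition_is_exhaustive_and_disjoint(self, rng):
        labels = rng.integers(0, 2, 200)
        parts = dirichlet_label_partition(labels, K=5, beta=0.5, seed=0)
        all_idx = np.concatenate(parts)
        assert len(all_idx) == 200
        assert len(np.unique(all_idx)) == 200

    def test_concentration_limit_approaches_global_fractions(self):
        labels = np.r_[np.zeros(300, int), np.ones(300, int)]
        parts = dirichlet_label_partition(labels, K=5, beta=1e6, seed=0)
        for idx in parts:
            assert abs(labels[idx].mean() - 0.5) < 0.05

    def test_low_beta_more_skewed_than_high_beta(self):
        """Mean pairwise total-variation across clients grows as beta shrinks."""
        labels = np.r_[np.zeros(500, int), np.ones(500, int)]

        def mean_tv(beta, seed):
            parts = dirichlet_label_partition(labels, K=10, beta=beta, seed=seed)
            fracs = [np.array([1 - labels[p].mean(), labels[p].mean()]) for p in parts]
            tvs = [
                0.5 * np.abs(fracs[i] - fracs[j]).sum()
                for i in range(10)
                for j in range(i + 1, 10)
            ]
            return np.mean(tvs)

        low = np.mean([mean_tv(0.1, s) for s in range(20)])
        high = np.mean([mean_tv(10.0, s) for s in range(20)])
        assert low > high

    def test_too_many_clients_rejected(self):
        with pytest.raises(ConfigurationError):
            dirichlet_label_partition(np.array([0, 1]), K=5, beta=0.5, seed=0)


class TestSyntheticGenerator:
    def test_stratified_label_count(self):
        ds = generate_synthetic_cxr(SyntheticConfig(n_images=100, prevalence=0.5, seed=0))
        assert ds.labels.sum() == 50

    def test_zero_effect_gives_chance_level_separation(self):
        ds = generate_synthetic_cxr(
            SyntheticConfig(n_images=500, effect_size=0.0, image_size=32, seed=0)
        )
        imgs = np.stack([ds.image(i) for i in range(len(ds))])
        feat = imgs[:, lung_field_mask(32)].mean(axis=1)
        acc = max(
            ((feat > np.median(feat)).astype(int) == ds.labels).mean(),
            ((feat < np.median(feat)).astype(int) == ds.labels).mean(),
        )
        assert abs(acc - 0.5) < 0.1

    def test_large_effect_separates_classes(self):
        cfg = SyntheticConfig(n_images=200, effect_size=0.25, noise_sd=0.05, image_size=32, seed=0)
        ds = generate_synthetic_cxr(cfg)
        imgs = np.stack([ds.image(i) for i in range(len(ds))])
        feat = imgs[:, lung_field_mask(32)].mean(axis=1)
        assert roc_auc(feat, ds.labels) > 0.95

    def test_separability_nondecreasing_in_effect_size(self):
        aucs = []
        for effect in (0.0, 0.1, 0.3):
            ds = generate_synthetic_cxr(
                SyntheticConfig(n_images=200, effect_size=effect, image_size=32, seed=7)
            )
            imgs = np.stack([ds.image(i) for i in range(len(ds))])
            feat = imgs[:, lung_field_mask(32)].mean(axis=1)
            aucs.append(roc_auc(feat, ds.labels))
        assert aucs[0] < 0.7 and aucs[1] <= aucs[2] + 0.02 and aucs[2] > 0.95

    def test_deterministic_per_seed(self):
        a = generate_synthetic_cxr(SyntheticConfig(n_images=5, image_size=16, seed=3))
        b = generate_synthetic_cxr(SyntheticConfig(n_images=5, image_size=16, seed=3))
        for i in range(5):
            np.testing.assert_array_equal(a.image(i), b.image(i))

    def test_partition_applies_client_shift(self):
        ds = generate_synthetic_cxr(SyntheticConfig(n_images=60, image_size=16, seed=0))
        imgs = np.stack([ds.image(i) for i in range(len(ds))])
        shards = partition_noniid(imgs, ds.labels, K=3, beta=10.0, seed=0, client_shift=0.2)
        means = [s.images.mean() for s in shards]
        assert np.std(means) > 0.01


class TestHeterogeneityScore:
    def test_identical_clients_score_zero(self):
        f = np.random.default_rng(0).normal(size=(10, 2))
        assert heterogeneity_score([f, f.copy()], method="identity") < 1e-12

    def test_hand_centroid_distance(self):
        a = np.array([[0.0, 0.0], [0.0, 0.0]])
        b = np.array([[2.0, 0.0]])
        assert heterogeneity_score([a, b], method="identity") == 2.0

    def test_skewed_partition_scores_higher_under_tsne(self):
        """Feature heterogeneity: beta=0.1 shards embed farther apart than
        near-IID shards when class signal dominates the features."""
        rng = np.random.default_rng(0)
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        feats = rng.normal(size=(200, 5)) + 4.0 * labels[:, None]

        def score(beta):
            parts = dirichlet_label_partition(labels, K=4, beta=beta, seed=1)
            return heterogeneity_score([feats[p] for p in parts], method="tsne", seed=0)

        assert score(0.1) > score(1e6)

    def test_single_client_rejected(self):
        with pytest.raises(ConfigurationError):
            heterogeneity_score([np.ones((3, 2))])
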