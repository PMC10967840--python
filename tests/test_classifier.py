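import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheezekit import nn
from wheezekit.classifier import (ModelConfig, build_model, evaluate,
                                  feature_map_sizes, kfold_indices,
                                  scores_to_metrics, split_dataset,
                                  spectrogram_features, train)
from wheezekit.melspec import mel_spectrogram


class TestSplits:
    def test_stratified_20_percent(self):
        y = np.array([0] * 50 + [1] * 50)
        train_idx, test_idx = split_dataset(y, 0.2, seed=0)
        assert test_idx.size == 20
        assert np.sum(y[test_idx]) == 10
        assert np.intersect1d(train_idx, test_idx).size == 0
        assert np.union1d(train_idx, test_idx).size == 100

    def test_split_determinism(self):
        y = np.array([0, 1] * 30)
        a = split_dataset(y, 0.2, seed=5)
        b = split_dataset(y, 0.2, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_small_or_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.array([0, 1, 0, 1, 0]), 0.2, seed=0)
        with pytest.raises(ValueError):
            split_dataset(np.ones(20), 0.2, seed=0)

    def test_grouped_split_keeps_groups_together(self):
        y = np.array([0, 0, 0, 1, 1, 1] * 10)
        groups = np.repeat(np.arange(20), 3)
        train_idx, test_idx = split_dataset(y, 0.2, seed=1, groups=groups)
        assert set(groups[train_idx]) & set(groups[test_idx]) == set()

    @pytest.mark.parametrize("n,sizes", [(80, {16}), (82, {16, 17})])
    def test_kfold_sizes(self, n, sizes):
        y = np.arange(n) % 2
        folds = kfold_indices(y, k=5, seed=0)
        assert {f.size for f in folds} <= sizes
        assert sum(f.size for f in folds) == n
        all_idx = np.concatenate(folds)
        assert np.unique(all_idx).size == n   # disjoint + exhaustive

    def test_kfold_rejects_oversized_k(self):
        with pytest.raises(ValueError):
            kfold_indices(np.array([0, 1, 0]), k=5, seed=0)


class TestShapes:
    def test_reference_shape_arithmetic(self):
        assert feature_map_sizes((64, 194)) == [(31, 96), (14, 47), (6, 22),
                                                (2, 10)]

    def test_tiny_input_raises_named_shape_error(self):
        with pytest.raises(nn.ShapeError, match="block"):
            feature_map_sizes((8, 8))
        with pytest.raises(nn.ShapeError):
            build_model(ModelConfig(), (8, 8))

    @given(st.integers(min_value=10, max_value=128),
           st.integers(min_value=10, max_value=200))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_shape_arithmetic_matches_hand_recursion(self, h, w):
        def hand(h, w):
            sizes = []
            for _ in range(4):
                h, w = h - 2, w - 2
                if h < 1 or w < 1:
                    return None
                h, w = h // 2, w // 2
                if h < 1 or w < 1:
                    return None
                sizes.append((h, w))
            return sizes

        expected = hand(h, w)
        if expected is None:
            with pytest.raises(nn.ShapeError):
                feature_map_sizes((h, w))
        else:
            assert feature_map_sizes((h, w)) == expected

    def test_model_forward_shape_and_probability_range(self):
        config = ModelConfig(seed=3)
        model = build_model(config, (64, 46))
        x = np.random.default_rng(0).standard_normal((5, 1, 64, 46)) \
            .astype(np.float32)
        proba = nn.predict_proba(model, x)
        assert proba.shape == (5,)
        assert np.all((proba > 0) & (proba < 1))


class TestMetrics:
    def test_perfect_ranking(self):
        m = scores_to_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["roc_auc"] == 1.0
        assert m["accuracy"] == 1.0

    def test_constant_scores_give_half_auc(self):
        m = scores_to_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert m["roc_auc"] == pytest.approx(0.5)

    def test_confusion_arithmetic(self):
        scores = [0.9] * 45 + [0.1] * 5 + [0.2] * 40 + [0.8] * 10
        labels = [1] * 50 + [0] * 50
        m = scores_to_metrics(scores, labels)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.80)

    def test_single_class_auc_flagged(self):
        with pytest.warns(UserWarning, match="single-class"):
            m = scores_to_metrics([0.2, 0.8], [1, 1])
        assert np.isnan(m["roc_auc"])


class TestTraining:
    def small_data(self, n=60, shape=(46, 46), seed=0):
        """Tiny separable task: bright blob vs flat noise images."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 1, *shape)).astype(np.float32)
        y = (rng.random(n) < 0.5).astype(np.float32)
        x[y == 1, 0, 15:31, 15:31] += 4.0
        return x, y

    def test_learns_separable_blob_task(self):
        x, y = self.small_data(n=80)
        config = ModelConfig(seed=1, max_epochs=12, patience=3, batch_size=16)
        model = build_model(config, x.shape[2:])
        history = train(model, x[:60], y[:60], x[60:], y[60:], config)
        metrics = evaluate(model, x[60:], y[60:])
        assert metrics["accuracy"] >= 0.9
        assert history.best_epoch >= 0

    def test_patience_zero_stops_at_first_non_improvement(self):
        x, y = self.small_data(n=40)
        config = ModelConfig(seed=2, max_epochs=30, patience=0, batch_size=8)
        model = build_model(config, x.shape[2:])
        history = train(model, x[:30], y[:30], x[30:], y[30:], config)
        losses = history.val_loss
        # ran exactly until the first epoch that failed to improve
        assert history.stopped_epoch == len(losses) - 1
        if history.stopped_epoch < config.max_epochs - 1:
            assert losses[-1] >= min(losses[:-1]) - 1e-7

    def test_training_determinism(self):
        x, y = self.small_data(n=40)
        config = ModelConfig(seed=7, max_epochs=2, patience=5, batch_size=8)
        outs = []
        for _ in range(2):
            model = build_model(config, x.shape[2:])
            train(model, x[:30], y[:30], x[30:], y[30:], config)
            outs.append(nn.predict_proba(model, x[30:]))
        assert np.array_equal(outs[0], outs[1])

    def test_empty_data_rejected(self):
        x, y = self.small_data(n=20)
        config = ModelConfig(seed=0)
        model = build_model(config, x.shape[2:])
        with pytest.raises(ValueError):
            nn.fit(model, x[:0], y[:0], x, y)


class TestFeatures:
    def test_spectrogram_standardization(self):
        x = np.random.default_rng(3).standard_normal(int(5 * 8000))
        ms = mel_spectrogram(x, 8000.0, "air")
        feats = spectrogram_features([ms, ms])
        assert feats.shape[0] == 2 and feats.shape[1] == 1
        assert abs(float(feats[0].mean())) < 1e-5
        assert float(feats[0].std()) == pytest.approx(1.0, abs=1e-4)
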