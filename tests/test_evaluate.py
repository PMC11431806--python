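import numpy as np
import pandas as pd
import pytest

from pleoscore.evaluate import (
    DEFAULT_ABLATION_SUBSETS,
    ConfusionCounts,
    CVConfig,
    ablation,
    cross_validate_svm,
    metrics,
    per_class_confusion,
)


def brute_force_confusion(pred, truth, positive):
    tp = tn = fp = fn = 0
    for p, t in zip(pred, truth):
        if p == positive and t == positive:
            tp += 1
        elif p != positive and t != positive:
            tn += 1
        elif p == positive and t != positive:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


class TestConfusion:
    def test_perfect_prediction(self):
        c = per_class_confusion([1, 2, 3], [1, 2, 3], 1)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 2, 0, 0)

    def test_all_predicted_positive(self):
        c = per_class_confusion([1, 1, 1], [1, 2, 3], 1)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 2, 0, 0)

    def test_matches_brute_force(self, rng):
        pred = rng.integers(1, 4, size=100)
        truth = rng.integers(1, 4, size=100)
        for k in (1, 2, 3):
            c = per_class_confusion(pred, truth, k)
            assert (c.tp, c.tn, c.fp, c.fn) == brute_force_confusion(pred, truth, k)
            assert c.total == 100

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            per_class_confusion([1, 2], [1], 1)

    def test_tp_sums_to_correct_predictions(self, rng):
        pred = rng.integers(1, 4, size=200)
        truth = rng.integers(1, 4, size=200)
        total_tp = sum(per_class_confusion(pred, truth, k).tp for k in (1, 2, 3))
        assert total_tp == int((pred == truth).sum())


class TestMetrics:
    def test_perfect(self):
        m = metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "recall", "specificity", "precision", "f1"))

    def test_known_arithmetic(self):
        m = metrics(ConfusionCounts(tp=1, fp=2, tn=0, fn=0))
        assert m["precision"] == pytest.approx(1 / 3)
        assert m["recall"] == 1.0

    def test_f1_identity(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            p, r = m["precision"], m["recall"]
            expected = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
            assert m["f1"] == pytest.approx(expected)

    def test_undefined_ratios_flagged(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m["precision"] == 0.0 and m["recall"] == 0.0
        assert "precision" in m["undefined"] and "recall" in m["undefined"]

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


def make_blobs(rng, n=60, sigma=0.01):
    centers = {1: (0, 0), 2: (5, 5), 3: (-5, 5)}
    xs, ys = [], []
    for k, (cx, cy) in centers.items():
        xs.append(rng.normal((cx, cy), sigma, size=(n, 2)))
        ys.append(np.full(n, k))
    return np.vstack(xs), np.concatenate(ys)


class TestCrossValidation:
    def test_separable_blobs_perfect_accuracy(self, rng):
        x, y = make_blobs(rng)
        report = cross_validate_svm(x, y, CVConfig(seed=3))
        assert report.overall["accuracy"] == 1.0

    def test_shuffled_labels_near_chance(self):
        """Randomly permuted labels give ~1/3 accuracy on balanced 3-class."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(300, 2))
            y = np.repeat([1, 2, 3], 100)
            rng.shuffle(y)
            report = cross_validate_svm(x, y, CVConfig(seed=seed))
            accs.append(report.overall["recall"])
        assert abs(np.mean(accs) - 1 / 3) < 0.06

    def test_deterministic_at_fixed_seed(self, rng):
        x, y = make_blobs(rng, sigma=3.0)
        r1 = cross_validate_svm(x, y, CVConfig(seed=17))
        r2 = cross_validate_svm(x, y, CVConfig(seed=17))
        assert r1.per_class == r2.per_class
        assert r1.overall == r2.overall
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_fold_sizes_differ_by_at_most_one(self, rng):
        x, y = make_blobs(rng, n=41)
        report = cross_validate_svm(x, y, CVConfig(seed=1))
        sizes = np.bincount(report.fold_assignments)
        assert sizes.max() - sizes.min() <= 1

    def test_class_smaller_than_folds_raises(self, rng):
        x = rng.normal(size=(10, 2))
        y = np.array([1] * 8 + [2, 2])
        with pytest.raises(ValueError, match="stratified"):
            cross_validate_svm(x, y, CVConfig(n_folds=5))


class TestAblation:
    def test_single_subset_matches_direct_cv(self, rng):
        x, y = make_blobs(rng, sigma=2.0)
        df = pd.DataFrame(x, columns=["a", "b"])
        cfg = CVConfig(seed=5)
        grid = ablation(df, y, {"all": ["a", "b"]}, cfg)
        direct = cross_validate_svm(df[["a", "b"]], y, cfg)
        assert grid.loc[0, "f1_overall"] == pytest.approx(direct.overall["f1"])

    def test_informative_feature_dominates(self, rng):
        n = 60
        y = np.repeat([1, 2, 3], n)
        e_shape = np.concatenate([rng.normal(m, 0.3, n) for m in (0, 3, 6)])
        e_size = rng.normal(0, 1, 3 * n)  # pure noise
        df = pd.DataFrame({"e_size": e_size, "e_shape": e_shape})
        grid = ablation(
            df, y, {"e_size": ["e_size"], "e_shape": ["e_shape"]}, CVConfig(seed=2)
        ).set_index("features")
        assert grid.loc["e_shape", "f1_overall"] > grid.loc["e_size", "f1_overall"]

    def test_unknown_column_raises(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30)})
        y = np.repeat([1, 2, 3], 10)
        with pytest.raises(KeyError):
            ablation(df, y, {"bad": ["nope"]}, CVConfig(seed=0))

    def test_empty_subset_raises(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30)})
        y = np.repeat([1, 2, 3], 10)
        with pytest.raises(ValueError):
            ablation(df, y, {"empty": []}, CVConfig(seed=0))

    def test_default_grid_has_seven_rows(self):
        assert len(DEFAULT_ABLATION_SUBSETS) == 7
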