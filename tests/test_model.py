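import numpy as np
import pytest
from sklearn.datasets import make_blobs

from combowalk import (
    GTBConfig,
    compute_metrics,
    cross_validate,
    grid_search,
    train_gtb,
)
from oracles import auc_cutoff_sweep, auc_pair_count


def blobs(n=200, seed=0, sep=5.0):
    X, y = make_blobs(
        n_samples=n, centers=[(-sep, -sep), (sep, sep)], cluster_std=1.0,
        random_state=seed,
    )
    return X, y


class TestTrainGTB:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = blobs(200, seed=1)
        model = train_gtb(X, y, GTBConfig(n_trees=50, max_depth=3, rng_seed=0))
        acc = ((model.predict_scores(X) >= 0.5).astype(int) == y).mean()
        assert acc >= 0.99

    def test_scores_are_probabilities(self):
        X, y = blobs(100, seed=2)
        model = train_gtb(X, y, GTBConfig(n_trees=20, max_depth=2))
        s = model.predict_scores(X)
        assert np.all((s >= 0) & (s <= 1))

    def test_single_class_raises(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_gtb(X, np.ones(10))

    def test_paper_scale_config_is_valid(self):
        GTBConfig(n_trees=300, max_depth=13)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            GTBConfig(n_trees=0)
        with pytest.raises(ValueError):
            GTBConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            GTBConfig(subsample=1.5)

    def test_training_loss_monotone_in_stages(self):
        X, y = blobs(150, seed=3, sep=3.0)
        model = train_gtb(
            X, y, GTBConfig(n_trees=60, max_depth=2, subsample=1.0, rng_seed=0)
        )
        losses = model.staged_train_loss(X, y)
        assert np.all(np.diff(losses) <= 1e-12)

    def test_deterministic_given_seed(self):
        X, y = blobs(120, seed=4)
        cfg = GTBConfig(n_trees=30, max_depth=3, rng_seed=7)
        s1 = train_gtb(X, y, cfg).predict_scores(X)
        s2 = train_gtb(X, y, cfg).predict_scores(X)
        assert np.array_equal(s1, s2)


class TestComputeMetrics:
    def test_symmetric_confusion(self):
        # TP = TN = FP = FN = 25
        y = np.array([1] * 50 + [0] * 50)
        s = np.array([0.9] * 25 + [0.1] * 25 + [0.9] * 25 + [0.1] * 25)
        rep = compute_metrics(y, s)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (25, 25, 25, 25)
        assert rep.precision == 0.5
        assert rep.recall == 0.5
        assert rep.f_measure == 0.5
        assert rep.mcc == 0.0

    def test_perfect_ranking(self):
        y = np.array([1] * 5 + [0] * 5)
        s = np.array([0.9, 0.85, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1, 0.05])
        rep = compute_metrics(y, s)  # 0.5 separates perfectly here
        assert rep.auc == 1.0
        assert rep.mcc == 1.0

    def test_derived_auc_075(self):
        rep = compute_metrics(
            np.array([1, 0, 1, 0]), np.array([0.9, 0.7, 0.6, 0.2])
        )
        assert rep.auc == pytest.approx(0.75)

    def test_hand_enumerated_confusions(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0])
        s = np.array([0.8, 0.6, 0.3, 0.7, 0.4, 0.2, 0.1])
        rep = compute_metrics(y, s, threshold=0.5)
        # predictions: 1,1,0 | 1,0,0,0 -> TP=2 FN=1 FP=1 TN=3
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (2, 1, 1, 3)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f_measure == pytest.approx(2 / 3)
        expected_mcc = (2 * 3 - 1 * 1) / np.sqrt(3 * 3 * 4 * 4)
        assert rep.mcc == pytest.approx(expected_mcc)

    def test_zero_denominator_flagged(self):
        rep = compute_metrics(np.array([0, 0, 1]), np.array([0.1, 0.2, 0.3]))
        assert rep.precision == 0.0
        assert "precision" in rep.degenerate

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_metrics(np.array([0, 1]), np.array([0.5]))

    def test_auc_equals_pair_count_and_cutoff_sweep_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            # quantized scores force ties
            s = np.round(rng.random(n), 1)
            rep = compute_metrics(y, s)
            assert rep.auc == pytest.approx(auc_pair_count(y, s), abs=1e-12)
            assert rep.auc == pytest.approx(auc_cutoff_sweep(y, s), abs=1e-12)

    def test_mcc_sign_symmetries(self):
        y = np.array([1, 1, 0, 0, 1, 0, 1, 0])
        s = np.array([0.9, 0.3, 0.6, 0.1, 0.8, 0.7, 0.55, 0.2])
        rep = compute_metrics(y, s)
        flipped = compute_metrics(y, 1 - s)
        assert flipped.mcc == pytest.approx(-rep.mcc)
        both = compute_metrics(1 - y, 1 - s)
        assert both.mcc == pytest.approx(rep.mcc)


class TestCrossValidate:
    def test_separable_data_auc_one(self):
        X, y = blobs(100, seed=5)
        rep = cross_validate(X, y, GTBConfig(n_trees=30, max_depth=2), k=5, seed=0)
        assert rep.auc == pytest.approx(1.0)
        assert len(rep.per_fold) == 5

    def test_label_permutation_null(self):
        rng = np.random.default_rng(123)
        X = rng.random((400, 10))
        y = np.array([0, 1] * 200)
        rep = cross_validate(
            X, rng.permutation(y), GTBConfig(n_trees=40, max_depth=2), k=10, seed=0
        )
        assert abs(rep.auc - 0.5) <= 0.08

    def test_fold_sizes_differ_by_at_most_one(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 53 + [1] * 47)
        sizes = [
            len(test)
            for _, test in StratifiedKFold(
                n_splits=10, shuffle=True, random_state=0
            ).split(np.zeros((100, 1)), y)
        ]
        assert max(sizes) - min(sizes) <= 1

    def test_reproducible_and_seed_sensitivity(self):
        X, y = blobs(150, seed=6)
        cfg = GTBConfig(n_trees=25, max_depth=2, rng_seed=1)
        r1 = cross_validate(X, y, cfg, k=5, seed=3)
        r2 = cross_validate(X, y, cfg, k=5, seed=3)
        assert r1.per_fold == r2.per_fold
        r3 = cross_validate(X, y, cfg, k=5, seed=4)
        assert r3.auc >= 0.95  # separable data robust to fold assignment

    def test_infeasible_stratification(self):
        X = np.zeros((12, 2))
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError, match="infeasible"):
            cross_validate(X, y, GTBConfig(n_trees=5, max_depth=1), k=5)

    def test_custom_scorer_factory_hook(self):
        from sklearn.linear_model import LogisticRegression

        class LRScorer:
            def __init__(self, X, y):
                self.est = LogisticRegression().fit(X, y)

            def predict_scores(self, X):
                return self.est.predict_proba(X)[:, 1]

        X, y = blobs(100, seed=7)
        rep = cross_validate(X, y, lambda X, y: LRScorer(X, y), k=5, seed=0)
        assert rep.auc == pytest.approx(1.0)


class TestGridSearch:
    def test_singleton_grid(self):
        X, y = blobs(60, seed=8)
        cfg = GTBConfig(n_trees=10, max_depth=2)
        assert grid_search(X, y, [cfg], folds=3, seed=0).n_trees == 10

    def test_strong_config_beats_degenerate(self):
        # overlapping blobs: a lone stump cannot rank them well
        X, y = make_blobs(
            n_samples=200, centers=[(-1, -1), (1, 1)], cluster_std=1.8,
            random_state=9,
        )
        weak = GTBConfig(n_trees=1, max_depth=1, learning_rate=0.01)
        strong = GTBConfig(n_trees=60, max_depth=3)
        best = grid_search(X, y, [weak, strong], folds=5, seed=0)
        assert best.n_trees == 60

    def test_deterministic_selection(self):
        X, y = blobs(100, seed=10, sep=2.0)
        grid = [
            GTBConfig(n_trees=10, max_depth=1),
            GTBConfig(n_trees=20, max_depth=2),
        ]
        assert grid_search(X, y, grid, folds=3, seed=5) == grid_search(
            X, y, grid, folds=3, seed=5
        )

    def test_empty_grid(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search(np.zeros((4, 1)), np.array([0, 1, 0, 1]), [])
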