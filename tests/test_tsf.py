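"""Interval sampling, summary features and the interval forest."""

import numpy as np
import pytest

from thermoseries.tsf import (
    DEFAULT_GRID,
    ForestConfig,
    IntervalSpec,
    TimeSeriesForest,
    _Node,
    fit_forest,
    grid_search,
    interval_summary,
    sample_intervals,
    tree_features,
)


def separable_tensor(n=20, m=12, v=2, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    x = rng.normal(size=(n, m, v))
    x[y == 1, :, 0] += gap
    return x, y


class TestSampleIntervals:
    def test_heuristic_interval_count(self):
        assert ForestConfig().resolve_k(20) == 4  # round(sqrt(20))

    def test_full_length_forced(self):
        rng = np.random.default_rng(0)
        specs = sample_intervals(20, 3, 20, rng)
        assert all(s.start == 1 and s.end == 20 for s in specs)

    def test_deterministic_given_seed(self):
        a = sample_intervals(20, 4, 3, np.random.default_rng(5), n_vars=3)
        b = sample_intervals(20, 4, 3, np.random.default_rng(5), n_vars=3)
        assert a == b

    def test_bounds_and_errors(self):
        rng = np.random.default_rng(1)
        for s in sample_intervals(20, 50, 3, rng):
            assert 1 <= s.start < s.end <= 20
            assert s.length >= 3
        with pytest.raises(ValueError):
            sample_intervals(5, 2, 6, rng)
        with pytest.raises(ValueError):
            IntervalSpec(0, 3, 3)


class TestIntervalSummary:
    def test_arithmetic_ramp(self):
        mu, sd, beta = interval_summary(np.array([1.0, 2, 3, 4, 5]), IntervalSpec(0, 1, 5))
        assert mu == pytest.approx(3.0)
        assert sd == pytest.approx(1.5811, abs=1e-4)
        assert beta == pytest.approx(1.0)

    def test_constant_series(self):
        mu, sd, beta = interval_summary(np.full(8, 2.5), IntervalSpec(0, 2, 6))
        assert (mu, sd, beta) == (2.5, 0.0, 0.0)

    def test_reversed_ramp_flips_slope_only(self):
        fwd = interval_summary(np.arange(5.0), IntervalSpec(0, 1, 5))
        rev = interval_summary(np.arange(5.0)[::-1], IntervalSpec(0, 1, 5))
        assert rev[0] == fwd[0] and rev[1] == fwd[1]
        assert rev[2] == pytest.approx(-fwd[2])


class TestTreeFeatures:
    @pytest.mark.parametrize("k, v, expected", [(2, 5, 30), (4, 5, 60), (1, 1, 3)])
    def test_vector_length_is_3kv(self, k, v, expected):
        rng = np.random.default_rng(0)
        intervals = sample_intervals(20, k, 3, rng, n_vars=v)
        xi = rng.normal(size=(20, v))
        assert tree_features(xi, intervals).shape == (expected,)

    def test_length_property_over_grid(self):
        rng = np.random.default_rng(1)
        for k in (1, 2, 3):
            for v in (1, 2, 5):
                intervals = sample_intervals(10, k, 2, rng, n_vars=v)
                xi = rng.normal(size=(10, v))
                assert tree_features(xi, intervals).size == 3 * k * v


def oracle_tree(x, y):
    """Independent exhaustive-enumeration CART with entropy gain.

    Mirrors the documented contract (midpoint thresholds, first-feature /
    lowest-threshold tie-break, majority leaves with ties to 0) using plain
    loops, to cross-check the vectorized implementation.
    """

    def entropy(labels):
        if len(labels) == 0:
            return 0.0
        p = np.mean(labels)
        h = 0.0
        for pi in (p, 1 - p):
            if pi > 0:
                h -= pi * np.log2(pi)
        return h

    def majority(labels):
        return 1 if np.sum(labels) * 2 > len(labels) else 0

    def build(xs, ys):
        if len(set(ys)) < 2:
            return ("leaf", majority(ys))
        best = None
        for f in range(xs.shape[1]):
            vals = sorted(set(xs[:, f]))
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left = ys[xs[:, f] <= thr]
                right = ys[xs[:, f] > thr]
                gain = entropy(ys) - (
                    len(left) * entropy(left) + len(right) * entropy(right)
                ) / len(ys)
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, f, thr)
        if best is None or best[0] <= 0:
            return ("leaf", majority(ys))
        _, f, thr = best
        mask = xs[:, f] <= thr
        return ("split", f, thr, build(xs[mask], ys[mask]), build(xs[~mask], ys[~mask]))

    def predict(node, row):
        while node[0] == "split":
            _, f, thr, left, right = node
            node = left if row[f] <= thr else right
        return node[1]

    root = build(x, y)
    return lambda rows: np.array([predict(root, r) for r in rows])


class TestForest:
    def test_matches_brute_force_oracle_on_toy_series(self):
        # 6 subjects, fixed full-length intervals (min_interval = M forces
        # deterministic interval choice), 2 trees
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 4, 2))
        y = np.array([0, 1, 0, 1, 1, 0])
        cfg = ForestConfig(n_trees=2, min_interval=4, k=1, seed=0)
        forest = fit_forest(x, y, cfg)
        intervals = [IntervalSpec(0, 1, 4), IntervalSpec(1, 1, 4)]
        feats = np.array([tree_features(xi, intervals) for xi in x])
        oracle = oracle_tree(feats, y)
        test_x = rng.normal(size=(10, 4, 2))
        test_feats = np.array([tree_features(xi, intervals) for xi in test_x])
        np.testing.assert_array_equal(forest.predict(test_x), oracle(test_feats))

    def test_separable_training_accuracy(self):
        x, y = separable_tensor()
        forest = fit_forest(x, y, ForestConfig(n_trees=10, seed=0))
        assert (forest.predict(x) == y).all()

    def test_single_class_rejected(self):
        x, _ = separable_tensor()
        with pytest.raises(ValueError):
            fit_forest(x, np.zeros(len(x), int), ForestConfig())

    def test_deterministic_given_seed(self):
        x, y = separable_tensor(gap=0.5)
        a = fit_forest(x, y, ForestConfig(n_trees=20, seed=9)).predict_scores(x)
        b = fit_forest(x, y, ForestConfig(n_trees=20, seed=9)).predict_scores(x)
        np.testing.assert_array_equal(a, b)

    def test_vote_tie_goes_to_control(self):
        x, y = separable_tensor(n=6, m=6)
        forest = fit_forest(x, y, ForestConfig(n_trees=2, min_interval=6, k=1, seed=0))
        # hand-built two-stump disagreement: scores 0.5 must map to control
        leaf1 = _Node(label=1)
        leaf0 = _Node(label=0)
        forest.trees_ = [leaf1, leaf0]
        scores = forest.predict_scores(x[:2])
        np.testing.assert_array_equal(scores, [0.5, 0.5])
        np.testing.assert_array_equal(forest.predict(x[:2]), [0, 0])

    def test_unanimous_votes_give_extreme_scores(self):
        x, y = separable_tensor()
        forest = fit_forest(x, y, ForestConfig(n_trees=15, seed=0))
        scores = forest.predict_scores(x)
        assert set(np.round(scores[y == 1], 6)) <= {1.0} or scores[y == 1].min() > 0.5

    def test_shape_mismatch_rejected(self):
        x, y = separable_tensor()
        forest = fit_forest(x, y, ForestConfig(n_trees=3, seed=0))
        with pytest.raises(ValueError):
            forest.predict(x[:, :5, :])
        with pytest.raises(RuntimeError):
            TimeSeriesForest(ForestConfig()).predict(x)


class TestGridSearch:
    def test_default_grid_evaluates_nine_combinations(self):
        x, y = separable_tensor(n=20, m=10)
        grid = {"n_trees": (5, 10, 15), "min_interval": (3, 5, 7)}
        best, table = grid_search(x, y, grid=grid, folds=5, seed=0)
        assert len(table) == 9
        assert len(DEFAULT_GRID["n_trees"]) * len(DEFAULT_GRID["min_interval"]) == 9

    def test_tie_rule_prefers_smaller_model(self):
        x, y = separable_tensor(n=20, m=10, gap=6.0)  # all combos perfect
        grid = {"n_trees": (5, 10), "min_interval": (3, 5)}
        best, table = grid_search(x, y, grid=grid, folds=5, seed=0)
        assert (table["mean_accuracy"] == 1.0).all()
        assert best.n_trees == 5 and best.min_interval == 3

    def test_single_cell_grid(self):
        x, y = separable_tensor(n=10, m=8)
        best, table = grid_search(
            x, y, grid={"n_trees": (7,), "min_interval": (4,)}, folds=2, seed=0
        )
        assert len(table) == 1
        assert best.n_trees == 7 and best.min_interval == 4


class TestTemporalImportance:
    def test_stump_forest_concentrates_mass_in_split_interval(self):
        x, y = separable_tensor(n=20, m=10, v=1, gap=5.0)
        cfg = ForestConfig(n_trees=5, min_interval=10, k=1, max_depth=1, seed=0)
        forest = fit_forest(x, y, cfg)
        imp = forest.temporal_importance()
        assert imp.values.sum() == pytest.approx(1.0)
        assert (imp.values >= 0).all()

    def test_mass_localizes_on_divergence_window(self):
        # classes differ only inside frames 8..13 of variable 0
        rng = np.random.default_rng(2)
        n, m = 40, 20
        y = np.arange(n) % 2
        x = rng.normal(size=(n, m, 2))
        x[y == 1, 8:14, 0] += 4.0
        forest = fit_forest(x, y, ForestConfig(n_trees=50, seed=1))
        imp = forest.temporal_importance()
        var, t = imp.argmax()
        assert var == 0
        assert 8 <= t <= 13

    def test_unfitted_forest_rejected(self):
        with pytest.raises(RuntimeError):
            TimeSeriesForest(ForestConfig()).temporal_importance()
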