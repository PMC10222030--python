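"""Gradient-boosted trees: splits, base learner, boosting, tuning, metrics."""

import itertools

import numpy as np
import pytest

from microrei.boosting import (
    DEFAULT_GRIDS,
    GradientBoostedTreeRegressor,
    evaluate,
    fit_tree,
    split_data,
    tune_sequential,
)


class TestSplitData:
    def test_87_gives_70_8_9(self):
        s = split_data(87, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (70, 8, 9)

    def test_disjoint_cover(self):
        s = split_data(53, seed=3)
        all_idx = np.concatenate([s.train, s.validation, s.test])
        assert sorted(all_idx) == list(range(53))

    def test_seed_deterministic(self):
        a, b = split_data(40, seed=9), split_data(40, seed=9)
        np.testing.assert_array_equal(a.train, b.train)
        assert not np.array_equal(split_data(40, seed=10).train, a.train)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_data(9)


class TestFitTree:
    def test_step_function_split_at_midpoint(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(float)
        tree = fit_tree(X, y, depth=1, min_node=1)
        # midpoint between the closest points straddling 0
        xs = np.sort(X[:, 0])
        gap = xs[np.searchsorted(xs, 0)]
        lo = xs[np.searchsorted(xs, 0) - 1]
        assert tree.threshold[0] == pytest.approx((gap + lo) / 2)
        assert np.sum((tree.predict(X) - y) ** 2) == pytest.approx(0.0)

    def test_matches_exhaustive_split_search(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        tree = fit_tree(X, y, depth=1, min_node=1)

        def sse(vals):
            return np.sum((vals - vals.mean()) ** 2) if len(vals) else 0.0

        best = (np.inf, None, None)
        for f in range(3):
            xs = np.sort(np.unique(X[:, f]))
            for a, b in zip(xs[:-1], xs[1:]):
                thr = (a + b) / 2
                left = y[X[:, f] < thr]
                right = y[X[:, f] >= thr]
                tot = sse(left) + sse(right)
                if tot < best[0] - 1e-12:
                    best = (tot, f, thr)
        assert tree.feature[0] == best[1]
        assert tree.threshold[0] == pytest.approx(best[2])

    def test_min_node_respected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        tree = fit_tree(X, y, depth=4, min_node=2)
        for node, f in enumerate(tree.feature):
            if f < 0:
                assert tree.cover[node] >= 2

    def test_constant_target_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        tree = fit_tree(X, np.ones(10), depth=3, min_node=1)
        assert tree.feature == [-1]


class TestBoosting:
    def test_interpolation_at_full_capacity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        m = GradientBoostedTreeRegressor(
            eta=1.0, depth=8, min_node=1, row_subsample=1.0, n_rounds=3
        ).fit(X, y)
        assert m.history_["train_rmse"].iloc[-1] < 1e-10

    def test_prediction_identity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        y = X[:, 0] + rng.normal(size=50)
        m = GradientBoostedTreeRegressor(n_rounds=15).fit(X, y)
        manual = np.full(50, m.base_score_)
        for tree in m.trees_:
            manual += m.eta * tree.predict(X)
        np.testing.assert_allclose(manual, m.predict(X), atol=1e-12)

    def test_training_rmse_non_increasing_full_sample(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] * 2 + rng.normal(size=60)
        m = GradientBoostedTreeRegressor(
            eta=0.3, depth=2, row_subsample=1.0, n_rounds=60
        ).fit(X, y)
        assert np.all(np.diff(m.history_["train_rmse"]) <= 1e-12)

    def test_validation_improves_with_planted_signal(self):
        from microrei.archetypes import ArchetypeGLRM, engineer_predictors
        from microrei.community import alpha_diversity_table, filter_core_asvs
        from microrei.simulate import CohortConfig, simulate_community

        cfg = CohortConfig(
            n_animals=200, n_asvs=150, n_components=4,
            module_sizes=(20, 15, 15, 10),
            component_effects=(5.0, -4.0, 3.0, 2.5), seed=11,
        )
        counts, truth = simulate_community(cfg)
        core = filter_core_asvs(counts)
        model = ArchetypeGLRM(n_components=12).fit(core.relative)
        pred, _ = engineer_predictors(model, alpha_diversity_table(core.relative))
        split = split_data(len(pred), seed=11)
        X = pred.to_numpy()
        y = truth.rei_true
        gbm = GradientBoostedTreeRegressor(n_rounds=26, random_state=11).fit(
            X[split.train], y[split.train],
            eval_set=(X[split.validation], y[split.validation]),
        )
        h = gbm.history_["validation_rmse"]
        assert h.iloc[25] < h.iloc[0]

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        p1 = GradientBoostedTreeRegressor(random_state=7).fit(X, y).predict(X)
        p2 = GradientBoostedTreeRegressor(random_state=7).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_shift_invariance_of_predictors(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 3))
        y = X[:, 1] + rng.normal(size=50) * 0.1
        m1 = GradientBoostedTreeRegressor(n_rounds=10, random_state=0).fit(X, y)
        X2 = X.copy()
        X2[:, 1] += 100.0
        m2 = GradientBoostedTreeRegressor(n_rounds=10, random_state=0).fit(X2, y)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X2), atol=1e-10)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        m = GradientBoostedTreeRegressor(n_rounds=5).fit(X, y)
        m2 = GradientBoostedTreeRegressor.from_dict(m.to_dict())
        np.testing.assert_allclose(m.predict(X), m2.predict(X), atol=0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GradientBoostedTreeRegressor(eta=0.0)
        with pytest.raises(ValueError):
            GradientBoostedTreeRegressor(depth=0)
        with pytest.raises(ValueError):
            GradientBoostedTreeRegressor(row_subsample=1.5)


class TestTuning:
    def test_interaction_target_needs_depth_two(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(150, 3))
        y = np.sign(X[:, 0]) * np.sign(X[:, 1]) + rng.normal(size=150) * 0.1
        params = tune_sequential(
            X[:100], y[:100], X[100:], y[100:],
            grids={"eta": (0.1,), "col_subsample": (1.0,),
                   "row_subsample": (1.0,), "min_node": (2,)},
            n_rounds=60, seed=0,
        )
        assert params["depth"] >= 2

    def test_singleton_grids_returned_unchanged(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        grids = {k: (v[0],) for k, v in DEFAULT_GRIDS.items()}
        grids["depth"] = (2,)
        params = tune_sequential(X[:30], y[:30], X[30:], y[30:], grids=grids,
                                 n_rounds=10, seed=0)
        for name, grid in grids.items():
            assert params[name] == grid[0]

    def test_tuning_deterministic(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(size=60) * 0.5
        kw = dict(grids={"eta": (0.05, 0.1), "col_subsample": (1.0,),
                         "row_subsample": (0.8, 1.0), "min_node": (2,),
                         "depth": (2, 3)}, n_rounds=15, seed=4)
        p1 = tune_sequential(X[:45], y[:45], X[45:], y[45:], **kw)
        p2 = tune_sequential(X[:45], y[:45], X[45:], y[45:], **kw)
        assert p1 == p2


class TestEvaluate:
    def test_perfect_model_r_one(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 1))
        y = np.arange(40.0)
        m = GradientBoostedTreeRegressor(
            eta=1.0, depth=8, min_node=1, row_subsample=1.0, n_rounds=3
        ).fit(X, np.sort(X[:, 0]))
        y = np.sort(X[:, 0])
        metrics = evaluate(m, X, y, split_data(40, seed=0))
        train = metrics[metrics["subset"] == "train"].iloc[0]
        assert train["pearson_r"] == pytest.approx(1.0)
        assert train["rmse"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_prediction_flagged_nan(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        m = GradientBoostedTreeRegressor(n_rounds=1).fit(X, np.ones(30))
        with pytest.warns(UserWarning, match="undefined Pearson"):
            metrics = evaluate(m, X, np.ones(30), split_data(30, seed=0))
        assert metrics["pearson_r"].isna().all()


def test_permutation_null_r_centered_at_zero():
    """Planted-signal fit beats the permutation-null test r distribution."""
    rng = np.random.default_rng(14)
    n = 120
    X = rng.normal(size=(n, 6))
    y = X[:, 0] * 2 + X[:, 1] - X[:, 2] + rng.normal(size=n) * 1.5
    split = split_data(n, seed=1)
    def test_r(target):
        m = GradientBoostedTreeRegressor(n_rounds=26, random_state=1).fit(
            X[split.train], target[split.train]
        )
        pred = m.predict(X[split.test])
        return np.corrcoef(pred, target[split.test])[0, 1]
    observed = test_r(y)
    null = [test_r(rng.permutation(y)) for _ in range(10)]
    assert abs(np.mean(null)) < 0.35
    assert observed > np.percentile(null, 95)
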