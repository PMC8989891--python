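"""Boosting core: oracle equivalence, CV selection, influence, PD, AUC."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from brtland import BoostedTreesClassifier, BRTConfig, compute_auc, fit_brt


# ---------------------------------------------------------------------------
# independent straight-line transcription of the boosting recursion
# ---------------------------------------------------------------------------


def _oracle_tree(X, z, w, depth, min_leaf=1):
    n = len(z)
    if depth == 0 or n < 2 * min_leaf or np.unique(z).size == 1:
        return ("leaf", z.sum() / max(w.sum(), 1e-12))
    base = ((z - z.mean()) ** 2).sum()
    best = None
    for j in range(X.shape[1]):
        vs = np.unique(X[:, j])
        for t in (vs[:-1] + vs[1:]) / 2.0:
            left = X[:, j] <= t
            nl = left.sum()
            if nl < min_leaf or n - nl < min_leaf:
                continue
            sse = ((z[left] - z[left].mean()) ** 2).sum() + (
                (z[~left] - z[~left].mean()) ** 2
            ).sum()
            if best is None or sse < best[0] - 1e-12:
                best = (sse, j, t, left)
    if best is None or base - best[0] <= 1e-12:
        return ("leaf", z.sum() / max(w.sum(), 1e-12))
    _, j, t, left = best
    return (
        "split", j, t,
        _oracle_tree(X[left], z[left], w[left], depth - 1, min_leaf),
        _oracle_tree(X[~left], z[~left], w[~left], depth - 1, min_leaf),
    )


def _oracle_apply(node, x):
    while node[0] == "split":
        node = node[3] if x[node[1]] <= node[2] else node[4]
    return node[1]


def _oracle_boost(X, y, n_trees, lr, depth):
    p_bar = y.mean()
    F = np.full(len(y), math.log(p_bar / (1 - p_bar)))
    for _ in range(n_trees):
        p = 1.0 / (1.0 + np.exp(-F))
        z = y - p
        w = p * (1 - p)
        tree = _oracle_tree(X, z, w, depth)
        F = F + lr * np.array([_oracle_apply(tree, xi) for xi in X])
    return 1.0 / (1.0 + np.exp(-F))


class TestBoostingOracle:
    @pytest.mark.parametrize("depth,n_trees", [(1, 2), (1, 3), (2, 2), (2, 3)])
    def test_matches_straightline_recursion(self, hand_xy, depth, n_trees):
        X, y = hand_xy
        est = BoostedTreesClassifier(
            learning_rate=0.1, tree_complexity=depth, bag_fraction=1.0,
            max_trees=n_trees, min_obs_in_node=1, select_trees="fixed",
            random_state=0,
        )
        est.fit(X, y)
        expected = _oracle_boost(X, y, n_trees, 0.1, depth)
        np.testing.assert_allclose(est.predict_proba(X)[:, 1], expected, atol=1e-10)

    def test_oracle_equivalence_on_20_row_instance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        y = (X[:, 1] - 0.3 * X[:, 2] + 0.4 * rng.normal(size=20) > 0).astype(float)
        est = BoostedTreesClassifier(
            learning_rate=0.1, tree_complexity=2, bag_fraction=1.0,
            max_trees=3, min_obs_in_node=1, select_trees="fixed", random_state=0,
        )
        est.fit(X, y)
        expected = _oracle_boost(X, y, 3, 0.1, 2)
        np.testing.assert_allclose(est.predict_proba(X)[:, 1], expected, atol=1e-10)


class TestFitContract:
    def test_training_deviance_nonincreasing_at_full_bag(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] > 0).astype(float)
        est = BoostedTreesClassifier(
            learning_rate=0.1, tree_complexity=2, bag_fraction=1.0,
            max_trees=50, min_obs_in_node=5, select_trees="fixed", random_state=0,
        )
        est.fit(X, y)
        assert np.all(np.diff(est.train_deviance_path_) <= 1e-12)

    def test_separable_binary_covariate_saturates(self):
        X = np.repeat([[0.0], [1.0]], 20, axis=0)
        y = X[:, 0]
        est = BoostedTreesClassifier(
            learning_rate=0.1, tree_complexity=1, bag_fraction=1.0,
            max_trees=300, min_obs_in_node=1, select_trees="fixed", random_state=0,
        )
        est.fit(X, y)
        p = est.predict_proba(X)[:, 1]
        assert p[y == 1].min() > 0.99 and p[y == 0].max() < 0.01

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="2 classes"):
            BoostedTreesClassifier().fit(X, np.ones(10))

    def test_nonfinite_covariates_rejected(self):
        X = np.zeros((10, 2))
        X[0, 0] = np.nan
        y = np.arange(10) % 2
        with pytest.raises(ValueError, match="finite"):
            BoostedTreesClassifier().fit(X, y)

    def test_predictions_strictly_inside_unit_interval(self, fitted_small_model, small_table):
        cols = [c for c in small_table.columns if c not in ("cell_id", "row", "col", "label")]
        p = fitted_small_model.predict_proba(small_table[cols])[:, 1]
        assert (p > 0).all() and (p < 1).all()

    def test_zero_trees_balanced_labels_predict_half(self, hand_xy):
        X, _ = hand_xy
        y = np.arange(10) % 2
        est = BoostedTreesClassifier(max_trees=1, min_obs_in_node=1,
                                     select_trees="fixed", random_state=0)
        est.fit(X, y)
        est.n_trees_ = 0  # intercept-only model
        np.testing.assert_allclose(est.predict_proba(X)[:, 1], 0.5, atol=1e-12)


class TestCVSelection:
    def test_pure_noise_selects_minimum_and_matches_null_deviance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        y = rng.integers(0, 2, size=200).astype(float)
        est = BoostedTreesClassifier(
            learning_rate=0.01, tree_complexity=2, bag_fraction=0.75,
            n_folds=10, step_size=25, max_trees=200, min_obs_in_node=10,
            patience=2, select_trees="cv", random_state=1,
        )
        est.fit(X, y)
        assert est.n_trees_ <= 2 * est.step_size
        p_bar = y.mean()
        null = -2 * (p_bar * math.log(p_bar) + (1 - p_bar) * math.log(1 - p_bar))
        assert est.cv_profile_["cv_deviance"].min() == pytest.approx(null, rel=0.05)

    def test_informative_covariate_beats_null_deviance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] > 0).astype(float)
        est = BoostedTreesClassifier(
            learning_rate=0.05, tree_complexity=2, step_size=25, max_trees=200,
            patience=2, select_trees="cv", random_state=1,
        )
        est.fit(X, y)
        null = 2 * math.log(2)  # balanced labels
        assert est.cv_profile_["cv_deviance"].min() < 0.5 * null

    def test_identical_seed_identical_selection(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 3))
        y = rng.integers(0, 2, size=150)
        kw = dict(learning_rate=0.02, tree_complexity=2, step_size=25, max_trees=100,
                  patience=2, select_trees="cv", random_state=42)
        a = BoostedTreesClassifier(**kw).fit(X, y)
        b = BoostedTreesClassifier(**kw).fit(X, y)
        assert a.n_trees_ == b.n_trees_
        pd.testing.assert_frame_equal(a.cv_profile_, b.cv_profile_)

    def test_fewer_rows_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.arange(6) % 2
        with pytest.raises(ValueError, match="folds"):
            BoostedTreesClassifier(n_folds=10).fit(X, y)


class TestRelativeInfluence:
    def test_sums_to_100(self, fitted_small_model):
        assert fitted_small_model.relative_influence().sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_covariate_gets_100(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 1))
        y = (X[:, 0] > 0).astype(float)
        est = BoostedTreesClassifier(learning_rate=0.1, tree_complexity=1, bag_fraction=1.0,
                                     max_trees=20, min_obs_in_node=5,
                                     select_trees="fixed", random_state=0)
        est.fit(X, y)
        assert est.relative_influence().iloc[0] == pytest.approx(100.0)

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=["a", "b", "c"])
        y = (X["a"] + 0.5 * X["b"] + 0.3 * rng.normal(size=150) > 0).astype(int)
        kw = dict(learning_rate=0.1, tree_complexity=2, bag_fraction=1.0,
                  max_trees=30, min_obs_in_node=5, select_trees="fixed", random_state=0)
        ri1 = BoostedTreesClassifier(**kw).fit(X, y).relative_influence()
        ri2 = BoostedTreesClassifier(**kw).fit(X[["c", "a", "b"]], y).relative_influence()
        for name in "abc":
            assert ri1[name] == pytest.approx(ri2[name], abs=1e-8)

    def test_no_splits_rejected(self, hand_xy):
        X, _ = hand_xy
        y = np.arange(10) % 2
        est = BoostedTreesClassifier(max_trees=1, min_obs_in_node=1,
                                     select_trees="fixed", random_state=0)
        est.fit(X, y)
        est.n_trees_ = 0
        with pytest.raises(ValueError, match="no splits"):
            est.relative_influence()


class TestPartialDependence:
    def test_unused_variable_gives_flat_curve(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"signal": rng.normal(size=120), "inert": rng.normal(size=120)})
        y = (X["signal"] > 0).astype(int)
        est = BoostedTreesClassifier(learning_rate=0.1, tree_complexity=1, bag_fraction=1.0,
                                     max_trees=20, min_obs_in_node=5,
                                     select_trees="fixed", random_state=0)
        est.fit(X, y)
        curve = est.partial_dependence("inert")
        assert curve["response"].std() == pytest.approx(0.0, abs=1e-12)

    def test_single_depth1_tree_is_step_function(self, hand_xy):
        X, y = hand_xy
        est = BoostedTreesClassifier(learning_rate=0.5, tree_complexity=1, bag_fraction=1.0,
                                     max_trees=1, min_obs_in_node=1,
                                     select_trees="fixed", random_state=0)
        est.fit(X, y)
        rec = est.trees_[0]
        var = int(rec.feature[0])
        thr = rec.threshold[0]
        curve = est.partial_dependence(f"x{var}", grid=np.linspace(-3, 3, 101))
        resp = curve["response"].to_numpy()
        g = curve.iloc[:, 0].to_numpy()
        assert len(np.unique(np.round(resp, 12))) == 2
        assert np.unique(resp[g <= thr]).size == 1 and np.unique(resp[g > thr]).size == 1

    def test_fixed_mode_equals_direct_prediction_on_constructed_rows(self, fitted_small_model):
        model = fitted_small_model
        grid = np.linspace(0, 30, 7)
        curve = model.partial_dependence("temperature", grid=grid)
        base = model._train_means_.copy()
        for c, m in model._train_modes_.items():
            base[c] = m
        rows = np.tile(base, (len(grid), 1))
        col = list(model.feature_names_in_).index("temperature")
        rows[:, col] = grid
        np.testing.assert_allclose(
            curve["response"], model.predict_proba(rows)[:, 1], atol=1e-12
        )

    def test_empty_grid_and_unknown_variable_rejected(self, fitted_small_model):
        with pytest.raises(ValueError, match="empty"):
            fitted_small_model.partial_dependence("temperature", grid=[])
        with pytest.raises(KeyError):
            fitted_small_model.partial_dependence("not_a_layer")

    def test_responses_on_probability_scale(self, fitted_small_model):
        curve = fitted_small_model.partial_dependence("vapor_pressure")
        assert curve["response"].between(0, 1).all()
        assert np.all(np.diff(curve["vapor_pressure"]) >= 0)


class TestAUC:
    def test_four_pair_enumeration(self):
        # positives 0.9, 0.4 vs negatives 0.6, 0.2: 3 of 4 pairs concordant
        assert compute_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        assert compute_auc(y, s) == pytest.approx(compute_auc(y, np.exp(3 * s)), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = np.round(rng.random(200), 2)  # induce ties
        assert compute_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([1, 1], [0.1, 0.2])


class TestCategoricalAndSerialization:
    def test_categorical_soil_class_is_used(self, small_table):
        cfg = BRTConfig(learning_rate=0.05, tree_complexity=3, step_size=25,
                        max_trees=50, patience=2, seed=3)
        model = fit_brt(small_table, cfg, select_trees="fixed")
        assert "soil_class" in model.relative_influence().index

    def test_unknown_level_routes_with_heaviest_level(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({
            "cat": pd.Categorical(rng.integers(1, 4, size=120)),
            "cont": rng.normal(size=120),
        })
        X["cat"] = X["cat"].astype("category")
        y = (X["cat"].cat.codes.to_numpy() == 0).astype(int)
        est = BoostedTreesClassifier(learning_rate=0.1, tree_complexity=2, bag_fraction=1.0,
                                     max_trees=10, min_obs_in_node=5,
                                     select_trees="fixed", random_state=0)
        est.fit(X, y)
        novel = pd.DataFrame({"cat": [99.0], "cont": [0.0]})
        p = est.predict_proba(novel.astype(float))[:, 1]
        assert 0 < p[0] < 1

    def test_json_roundtrip_preserves_predictions(self, fitted_small_model, small_table):
        cols = [c for c in small_table.columns if c not in ("cell_id", "row", "col", "label")]
        X = small_table[cols]
        restored = BoostedTreesClassifier.from_json(fitted_small_model.to_json())
        np.testing.assert_allclose(
            restored.predict_proba(X.to_numpy(dtype=float))[:, 1],
            fitted_small_model.predict_proba(X)[:, 1],
            atol=1e-12,
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BRTConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            BRTConfig(bag_fraction=1.5)
        with pytest.raises(ValueError):
            BRTConfig(n_folds=1)
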