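"""Excursion statistics and the unit-blocked regression tree."""

import numpy as np
import pandas as pd
import pytest

from thermotactics import (
    GroupedRegressionTree,
    excursion_frequency,
    grouped_cv,
    grow_tree,
    permutation_test,
    prune_1se,
    select_size_1se,
    simulate_excursion_dataset,
    summarize_movement,
    travelled_distances,
)
from thermotactics.exceptions import (
    AmbiguousOrderError,
    DegenerateInputError,
    InvalidRequestError,
)
from thermotactics.movement_tree import CVResult


# ---------------------------------------------------------------------------
# independent brute-force oracle

def oracle_best_split(X, y, sse_node, min_leaf):
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals, vals[1:]):
            t = 0.5 * (a + b)
            mask = X[:, f] <= t
            nl, nr = mask.sum(), (~mask).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            sse = (np.sum((y[mask] - y[mask].mean()) ** 2)
                   + np.sum((y[~mask] - y[~mask].mean()) ** 2))
            red = sse_node - sse
            if best is None or red > best[0]:
                best = (red, f, t)
    return best


def oracle_tree(X, y, min_leaf, cp, sse_root):
    """Naive exhaustive CART, structured as (feature, threshold, children)."""
    sse_node = float(np.sum((y - y.mean()) ** 2))
    if y.size < 2 * min_leaf or sse_node <= 0:
        return ("leaf", y.size, float(y.mean()))
    best = oracle_best_split(X, y, sse_node, min_leaf)
    if best is None or (sse_root > 0 and best[0] / sse_root < cp):
        return ("leaf", y.size, float(y.mean()))
    _, f, t = best
    mask = X[:, f] <= t
    return ("split", f, t,
            oracle_tree(X[mask], y[mask], min_leaf, cp, sse_root),
            oracle_tree(X[~mask], y[~mask], min_leaf, cp, sse_root))


def assert_same_tree(node, oracle):
    if oracle[0] == "leaf":
        assert node.is_leaf
        assert node.n == oracle[1]
        assert node.mean == pytest.approx(oracle[2], abs=1e-9)
        return
    assert not node.is_leaf
    assert node.feature == oracle[1]
    assert node.threshold == pytest.approx(oracle[2], abs=1e-12)
    assert_same_tree(node.left, oracle[3])
    assert_same_tree(node.right, oracle[4])


# ---------------------------------------------------------------------------
# telemetry-derived statistics


class TestTravelledDistances:
    def _fixes(self, coords, start="2010-07-14 05:00"):
        ts = pd.date_range(start, periods=len(coords), freq="6h")
        return pd.DataFrame({
            "fish_id": "a", "timestamp": ts,
            "period": ["dawn", "day", "dusk", "night"][: len(coords)] * 1,
            "easting": [c[0] for c in coords],
            "northing": [c[1] for c in coords],
        })

    def test_three_four_five_triangle(self):
        steps, daily = travelled_distances(self._fixes([(0, 0), (300, 400)]))
        assert steps["distance"].tolist() == [500.0]
        assert daily["total_distance"].tolist() == [500.0]

    def test_single_fix_gives_no_steps(self):
        steps, daily = travelled_distances(self._fixes([(0, 0)]))
        assert steps.empty and daily.empty

    def test_square_walk(self):
        steps, daily = travelled_distances(
            self._fixes([(0, 0), (100, 0), (100, 100), (0, 100)]))
        assert steps["distance"].tolist() == [100.0, 100.0, 100.0]
        assert daily["total_distance"].tolist() == [300.0]

    def test_step_labelled_by_arrival_period(self):
        steps, _ = travelled_distances(self._fixes([(0, 0), (300, 400)]))
        assert steps["period"].tolist() == ["day"]

    def test_duplicate_timestamps_raise(self):
        df = self._fixes([(0, 0), (1, 1)])
        df.loc[1, "timestamp"] = df.loc[0, "timestamp"]
        with pytest.raises(AmbiguousOrderError):
            travelled_distances(df)


class TestExcursionFrequency:
    def _table(self, occupancy, date="2010-07-14"):
        n = len(occupancy)
        return pd.DataFrame({
            "fish_id": "a",
            "timestamp": pd.date_range(f"{date} 05:00", periods=n, freq="2h"),
            "in_epilimnion": occupancy,
        })

    def _layers(self):
        return pd.DataFrame({"date": ["2010-07-14"], "epi_mean": [23.0],
                             "meta_mean": [13.0]})

    def test_fraction_in_percent(self):
        out = excursion_frequency(self._table([True, True] + [False] * 6),
                                  self._layers())
        assert out["excursion_pct"].tolist() == [25.0]
        assert out["epi_mean"].tolist() == [23.0]
        assert out["day_of_year"].tolist() == [195]
        assert out["year"].tolist() == [2010]

    def test_zero_excursions(self):
        out = excursion_frequency(self._table([False] * 4), self._layers())
        assert out["excursion_pct"].tolist() == [0.0]

    def test_undefined_day_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="no fix with defined"):
            out = excursion_frequency(self._table([np.nan] * 4), self._layers())
        assert out.empty


class TestGrowTree:
    def test_constant_response_single_leaf(self):
        tm = grow_tree(np.arange(20.0)[:, None], np.full(20, 3.0), min_leaf=2)
        assert tm.leaf_count == 1
        assert tm.r2 == 0.0

    def test_step_function_split_at_grid_midpoint(self):
        x = np.round(np.arange(20.0, 26.0, 0.1), 1)
        y = np.where(x < 22.4, 5.0, 0.5)
        tm = grow_tree(x[:, None], y, min_leaf=5)
        assert tm.splits()[0]["value"] == pytest.approx(22.35, abs=1e-12)

    def test_stronger_predictor_wins_root(self, rng):
        n = 100
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = 3.0 * (a > 0) + 1.0 * (b > 0) + rng.normal(0, 0.1, n)
        tm = grow_tree(np.column_stack([a, b]), y, min_leaf=5)
        assert tm.splits()[0]["variable"] == "x0"

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 201))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n) + 2.0 * (X[:, 0] > 0.3)
        min_leaf = int(rng.integers(2, 8))
        tm = grow_tree(X, y, min_leaf=min_leaf, cp=0.01)
        sse_root = float(np.sum((y - y.mean()) ** 2))
        assert_same_tree(tm.root, oracle_tree(X, y, min_leaf, 0.01, sse_root))

    def test_matches_sklearn_root_threshold(self, rng):
        from sklearn.tree import DecisionTreeRegressor
        x = rng.uniform(20, 26, 300)
        y = np.where(x < 22.4, 30.0, 1.0) + rng.normal(0, 2.0, 300)
        tm = grow_tree(x[:, None], y, min_leaf=5, max_leaves=2)
        sk = DecisionTreeRegressor(max_leaf_nodes=2, min_samples_leaf=5,
                                   random_state=0).fit(x[:, None], y)
        # sklearn stores thresholds in float32, hence the loose tolerance
        assert tm.splits()[0]["value"] == pytest.approx(sk.tree_.threshold[0],
                                                        abs=1e-5)

    def test_r2_nondecreasing_along_subtree_sequence(self, rng):
        X = rng.normal(size=(150, 2))
        y = rng.normal(size=150) + (X[:, 0] > 0) + 0.5 * (X[:, 1] > 0.5)
        tm = grow_tree(X, y, min_leaf=5, cp=0.005)
        leaves = [s[1] for s in tm.subtrees]
        rel = [s[2] for s in tm.subtrees]
        order = np.argsort(leaves)
        assert all(np.diff(np.array(rel)[order]) <= 1e-9)  # error falls with size
        for s in tm.splits():
            assert s["sse_drop"] >= 0


class TestGroupedCV:
    def _data(self, seed=0, step=8.0):
        rng = np.random.default_rng(seed)
        units = np.repeat([f"u{i:02d}" for i in range(20)], 10)
        x = rng.uniform(20, 26, 200)
        y = np.where(x < 22.4, step, 0.0) + rng.normal(0, 1.0, 200)
        return pd.DataFrame({"epi": x}), y, units

    def test_folds_partition_whole_units(self):
        X, y, units = self._data()
        cv = grouped_cv(X, y, units, n_folds=10, seed=1)
        folds = pd.Series(cv.fold_of)
        assert folds.value_counts().tolist() == [2] * 10
        fold_per_obs = pd.Series(units).map(cv.fold_of)
        for u in np.unique(units):
            assert fold_per_obs[pd.Series(units) == u].nunique() == 1

    def test_same_seed_same_folds(self):
        X, y, units = self._data()
        a = grouped_cv(X, y, units, n_folds=10, seed=42)
        b = grouped_cv(X, y, units, n_folds=10, seed=42)
        assert a.fold_of == b.fold_of
        assert np.allclose(a.table["cv_error"], b.table["cv_error"])

    def test_too_many_folds(self):
        X, y, units = self._data()
        with pytest.raises(InvalidRequestError):
            grouped_cv(X, y, units, n_folds=30, seed=0)

    def test_strong_step_prefers_two_leaves(self):
        hits = 0
        for seed in range(5):
            X, y, units = self._data(seed=seed)
            tree = grow_tree(X, y, min_leaf=5, cp=0.01)
            cv = grouped_cv(X, y, units, n_folds=10, seed=seed, tree=tree)
            t = cv.table
            err1 = float(t.loc[t["n_leaves"] == 1, "cv_error"].iloc[0])
            err2 = float(t.loc[t["n_leaves"] == 2, "cv_error"].min()) \
                if (t["n_leaves"] == 2).any() else float(
                    t.loc[t["n_leaves"] > 1, "cv_error"].min())
            hits += err2 < err1
        assert hits >= 4


class TestPrune1SE:
    def test_hand_worked_example(self):
        idx = select_size_1se([1, 2, 3, 4], [1.00, 0.60, 0.55, 0.54],
                              [0.10, 0.06, 0.05, 0.05])
        assert [1, 2, 3, 4][idx] == 3

    def test_minimum_at_single_leaf(self):
        idx = select_size_1se([1, 2, 3], [0.5, 0.6, 0.7], [0.05, 0.05, 0.05])
        assert [1, 2, 3][idx] == 1

    def test_all_equal_errors_prefers_smallest(self):
        idx = select_size_1se([1, 2, 3], [0.5, 0.5, 0.5], [0.05, 0.05, 0.05])
        assert [1, 2, 3][idx] == 1

    def test_never_larger_than_minimizer(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(120, 2))
            y = r.normal(size=120) + 2 * (X[:, 0] > 0)
            units = np.repeat(np.arange(12), 10)
            tree = grow_tree(X, y, min_leaf=5, cp=0.005)
            cv = grouped_cv(X, y, units, n_folds=6, seed=seed, tree=tree)
            pruned = prune_1se(tree, cv)
            i_min = int(np.argmin(cv.table["cv_error"]))
            assert pruned.leaf_count <= int(cv.table["n_leaves"].iloc[i_min])

    def test_prune_1se_with_synthetic_cv_table(self, rng):
        X = rng.normal(size=(100, 1))
        y = 5.0 * (X[:, 0] > 0) + rng.normal(0, 0.5, 100)
        tree = grow_tree(X, y, min_leaf=5, cp=0.001)
        tbl = tree.subtrees
        cv = CVResult(table=pd.DataFrame({
            "alpha": [s[0] for s in tbl],
            "n_leaves": [s[1] for s in tbl],
            "cv_error": [1.0 if s[1] == 1 else 0.2 + 0.001 * s[1] for s in tbl],
            "cv_se": [0.05] * len(tbl),
        }), fold_of={}, n_folds=10, seed=0)
        pruned = prune_1se(tree, cv)
        assert pruned.leaf_count == min(s[1] for s in tbl if s[1] > 1)


class TestPermutationTest:
    def _signal_data(self, seed=0):
        df = simulate_excursion_dataset(n_fish=12, days=10, seed=seed,
                                        stagger_span=0)
        X = df[["epi_mean", "meta_mean"]]
        return X, df["excursion_pct"].to_numpy(), df["fish_id"].to_numpy()

    def test_strong_signal_minimal_p(self):
        X, y, units = self._signal_data()
        tree = grow_tree(X, y, min_leaf=10, max_leaves=2)
        res = permutation_test(tree, X, y, units, m=99, seed=5)
        assert res.p_value == pytest.approx(1.0 / 100.0)
        assert res.observed_r2 > max(res.null_r2)

    def test_reproducible_with_seed(self):
        X, y, units = self._signal_data()
        tree = grow_tree(X, y, min_leaf=10, max_leaves=2)
        a = permutation_test(tree, X, y, units, m=99, seed=7)
        b = permutation_test(tree, X, y, units, m=99, seed=7)
        assert np.array_equal(a.null_r2, b.null_r2)
        assert a.p_value == b.p_value

    def test_p_value_bounds(self):
        X, y, units = self._signal_data(seed=3)
        tree = grow_tree(X, y, min_leaf=10, max_leaves=2)
        res = permutation_test(tree, X, y, units, m=99, seed=1)
        assert 1.0 / 100.0 <= res.p_value <= 1.0

    def test_single_leaf_rejected(self):
        X, y, units = self._signal_data()
        tree = grow_tree(X, np.asarray(y), min_leaf=10, max_leaves=1)
        assert tree.leaf_count == 1
        with pytest.raises(InvalidRequestError):
            permutation_test(tree, X, y, units, m=99, seed=0)

    def test_constant_response_rejected(self):
        X, y, units = self._signal_data()
        tree = grow_tree(X, y, min_leaf=10, max_leaves=2)
        with pytest.raises(DegenerateInputError):
            permutation_test(tree, X, np.full_like(y, 5.0), units, m=99, seed=0)


class TestSummarizeMovement:
    def test_cell_means(self):
        steps = pd.DataFrame({"period": ["dawn", "dawn"], "distance": [100.0, 300.0]})
        out = summarize_movement(steps, ["below", "below"])
        cell = out[(out["period"] == "dawn") & (out["condition"] == "below")]
        assert cell["mean"].iloc[0] == 200.0
        assert cell["n"].iloc[0] == 2

    def test_empty_cells_reported(self):
        steps = pd.DataFrame({"period": ["day"], "distance": [50.0]})
        out = summarize_movement(steps, [False])
        above = out[out["condition"] == "above"]
        assert (above["n"] == 0).all()
        assert above["mean"].isna().all()


class TestGroupedRegressionTreeEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone
        est = GroupedRegressionTree(min_leaf=8, cp=0.02, n_folds=5, random_state=3)
        params = est.get_params()
        assert params["min_leaf"] == 8 and params["cp"] == 0.02
        clone(est)

    def test_fit_predict_recovers_thresholds(self):
        df = simulate_excursion_dataset(n_fish=16, days=25, seed=11)
        X = df[["epi_mean", "meta_mean", "day_of_year", "year"]]
        est = GroupedRegressionTree(random_state=1).fit(
            X, df["excursion_pct"], groups=df["fish_id"])
        assert est.leaf_count_ >= 2
        root = est.tree_.splits()[0]
        assert root["variable"] == "epi_mean"
        assert abs(root["value"] - 22.4) < 0.3
        pred = est.predict(X)
        assert pred.shape == (len(df),)
        assert est.score(X, df["excursion_pct"]) > 0.3

    def test_groups_required(self):
        df = simulate_excursion_dataset(n_fish=8, days=5, seed=0)
        with pytest.raises(InvalidRequestError):
            GroupedRegressionTree().fit(df[["epi_mean"]], df["excursion_pct"])
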