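"""Classification trees: splitting, surrogates, growing, CV pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfsid.errors import ValidationError
from calfsid.tree import (
    CartModel,
    SplitRule,
    TreeControls,
    best_split,
    extract_binary_predictors,
    find_surrogates,
    gini_impurity,
    grow_tree,
    prune_by_cv,
)


def brute_force_best_split(X: pd.DataFrame, y: np.ndarray, min_bucket: int):
    """Independent oracle: enumerate every (variable, midpoint) split and
    compute the Gini decrease directly from the definition."""

    def count_gini(yy):
        if len(yy) == 0:
            return 0.0
        p = yy.mean()
        return len(yy) * 2 * p * (1 - p)

    best = None
    for j, name in enumerate(X.columns):
        x = X[name].to_numpy(float)
        ok = ~np.isnan(x)
        xo, yo = x[ok], y[ok]
        if yo.size == 0 or yo.min() == yo.max():
            continue
        parent = count_gini(yo)
        for cut in np.unique(xo)[:-1]:
            mid = (cut + np.unique(xo)[np.searchsorted(np.unique(xo), cut) + 1]) / 2
            left = yo[xo < mid]
            right = yo[xo >= mid]
            if len(left) < min_bucket or len(right) < min_bucket:
                continue
            dec = parent - count_gini(left) - count_gini(right)
            if best is None or dec > best[0] + 1e-12:
                best = (dec, j, mid)
    return best


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((50, 50), 0.5), ((100, 0), 0.0), ((313, 1087), 2 * (313 / 1400) * (1087 / 1400))],
    )
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_node_rejected(self):
        with pytest.raises(ValidationError):
            gini_impurity((0, 0))


class TestBestSplit:
    def test_six_point_toy_cutpoint(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        y = np.array([1, 1, 0, 0, 0, 0])
        rule, dec = best_split(X, y, min_bucket=1)
        assert rule.cutpoint == 2.5
        assert dec > 0

    def test_perfect_separator_yields_pure_children(self):
        X = pd.DataFrame({"a": np.r_[np.zeros(10), np.ones(10)], "b": np.arange(20) % 3})
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        rule, _ = best_split(X, y, min_bucket=1)
        assert rule.variable == "a" and rule.cutpoint == 0.5

    def test_constant_variable_excluded(self):
        X = pd.DataFrame({"c": np.ones(20), "x": np.arange(20.0)})
        y = (np.arange(20) >= 10).astype(int)
        rule, _ = best_split(X, y, min_bucket=1)
        assert rule.variable == "x"

    def test_no_admissible_split_returns_none(self):
        X = pd.DataFrame({"c": np.ones(10)})
        assert best_split(X, np.r_[np.zeros(5), np.ones(5)].astype(int), 1) is None

    @given(st.integers(0, 300))
    @settings(max_examples=40)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 201))
        k = int(rng.integers(1, 5))
        X = pd.DataFrame(
            {f"v{j}": np.round(rng.normal(0, 1, n), 1) for j in range(k)}
        )
        y = rng.integers(0, 2, n)
        got = best_split(X, y, min_bucket=3)
        expected = brute_force_best_split(X, y, min_bucket=3)
        if expected is None:
            assert got is None
            return
        assert got is not None
        rule, dec = got
        assert dec == pytest.approx(expected[0], abs=1e-9)


class TestSurrogates:
    def test_duplicate_variable_perfect_agreement(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        X = pd.DataFrame({"x": x, "copy": x, "junk": rng.normal(size=60)})
        go_left = (x < 0).astype(float)
        surr = find_surrogates(X, go_left, "x")
        assert surr[0].variable == "copy"
        assert surr[0].agreement == pytest.approx(1.0)

    def test_all_missing_other_variables_empty(self):
        x = np.arange(20.0)
        X = pd.DataFrame({"x": x, "m": np.full(20, np.nan)})
        surr = find_surrogates(X, (x < 10).astype(float), "x")
        assert surr == []

    def test_eight_of_ten_agreement_retained(self):
        # primary sends 5 left / 5 right; B agrees on 8/10; baseline 5/10
        primary = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float)
        b = np.array([1, 2, 3, 4, 9, 5, 6, 7, 8, 0.5])  # b < 4.5 -> left matches 8
        X = pd.DataFrame({"p": np.zeros(10), "b": b})
        surr = find_surrogates(X, primary, "p")
        assert surr and surr[0].variable == "b"
        assert surr[0].agreement == pytest.approx(0.8)

    def test_below_baseline_not_retained(self):
        primary = np.array([1] * 9 + [0], dtype=float)  # baseline 0.9
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"p": np.zeros(10), "b": rng.normal(size=10)})
        surr = find_surrogates(X, primary, "p")
        assert all(s.agreement > 0.9 for s in surr)


class TestGrowTree:
    def test_pure_outcome_single_root(self):
        df = pd.DataFrame({"x": np.arange(50.0), "died": np.zeros(50, int)})
        tree = grow_tree(df, "died", ["x"])
        assert tree.is_leaf

    def test_below_min_split_terminal(self):
        df = pd.DataFrame({"x": np.arange(10.0), "died": [0, 1] * 5})
        tree = grow_tree(df, "died", ["x"], TreeControls(min_split=20))
        assert tree.is_leaf

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0), "died": np.arange(10)})
        with pytest.raises(ValidationError):
            grow_tree(df, "died", ["x"])

    def test_planted_two_rule_recovery(self, planted_tree_frame):
        res = CartModel(
            planted_tree_frame, "died", ["ph", "cns", "noise_a", "noise_b"]
        ).fit(seed=0)
        splits = {n.split.variable for n in res.tree_.internal_nodes()}
        assert splits == {"ph", "cns"}
        ph_cut = [n.split.cutpoint for n in res.tree_.internal_nodes() if n.split.variable == "ph"][0]
        assert abs(ph_cut - 6.85) < 0.05

    def test_child_counts_sum_to_parent(self, planted_tree_frame):
        tree = grow_tree(planted_tree_frame, "died", ["ph", "cns"])
        for node in tree.internal_nodes():
            assert node.left.n + node.right.n == node.n
            assert node.left.n_died + node.right.n_died == node.n_died

    def test_every_split_decreases_impurity(self, planted_tree_frame):
        tree = grow_tree(planted_tree_frame, "died", ["ph", "cns", "noise_a"])
        for node in tree.internal_nodes():
            parent = gini_impurity((node.n_survived, node.n_died)) * node.n
            child = sum(
                gini_impurity((c.n_survived, c.n_died)) * c.n
                for c in (node.left, node.right)
            )
            assert child < parent + 1e-9


class TestSurrogateRouting:
    def test_no_missing_data_predictions_unaffected_by_surrogates(self, planted_tree_frame):
        df = planted_tree_frame
        feats = ["ph", "cns", "noise_a", "noise_b"]
        with_s = grow_tree(df, "died", feats, TreeControls(max_surrogates=5))
        without = grow_tree(df, "died", feats, TreeControls(max_surrogates=0))
        records = df.to_dict("records")
        a = [with_s.route(r).predicted_risk for r in records]
        b = [without.route(r).predicted_risk for r in records]
        assert a == b

    def test_missing_primary_routed_by_perfect_surrogate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        df = pd.DataFrame({"x": x, "twin": x, "died": (x > 0).astype(int)})
        tree = grow_tree(df, "died", ["x", "twin"], TreeControls(min_split=10))
        rec_full = {"x": 2.0, "twin": 2.0}
        rec_missing = {"x": float("nan"), "twin": 2.0}
        assert tree.route(rec_full).predicted_risk == tree.route(rec_missing).predicted_risk


class TestPruning:
    def test_single_node_tree_unchanged_path_length_one(self):
        df = pd.DataFrame({"x": np.arange(50.0), "died": np.zeros(50, int)})
        tree = grow_tree(df, "died", ["x"])
        pruned, path = prune_by_cv(tree, df, "died", ["x"], seed=0)
        assert pruned.is_leaf and len(path.alphas) == 1

    def test_path_monotone_and_subtree(self, planted_tree_frame):
        df = planted_tree_frame
        feats = ["ph", "cns", "noise_a", "noise_b"]
        tree = grow_tree(df, "died", feats, TreeControls(cp=0.0001))
        pruned, path = prune_by_cv(tree, df, "died", feats, TreeControls(cp=0.0001), seed=1)
        alphas = np.array(path.alphas)
        assert (np.diff(alphas) > 0).all()
        sizes = np.array(path.n_leaves)
        assert (np.diff(sizes) <= 0).all()
        grown_ids = {n.id for n in tree.leaves()} | {n.id for n in tree.internal_nodes()}
        pruned_ids = {n.id for n in pruned.leaves()} | {n.id for n in pruned.internal_nodes()}
        assert pruned_ids <= grown_ids

    def test_fewer_cases_than_folds_rejected(self):
        df = pd.DataFrame({"x": np.arange(6.0), "died": [0, 1] * 3})
        tree = grow_tree(df, "died", ["x"], TreeControls(min_split=2, min_bucket=1))
        with pytest.raises(ValidationError):
            prune_by_cv(tree, df, "died", ["x"], folds=10)

    def test_fold_assignment_reproducible(self, planted_tree_frame):
        df = planted_tree_frame
        feats = ["ph", "cns"]
        tree = grow_tree(df, "died", feats)
        _, p1 = prune_by_cv(tree, df, "died", feats, seed=5)
        _, p2 = prune_by_cv(tree, df, "died", feats, seed=5)
        assert p1.cv_error == p2.cv_error


class TestExtractBinaryPredictors:
    def test_orientation_and_naming(self, planted_tree_frame):
        res = CartModel(planted_tree_frame, "died", ["ph", "cns"]).fit(seed=0)
        preds = res.extract_binary_predictors()
        by_var = {p["variable"]: p for p in preds}
        assert by_var["ph"]["op"] == "lt"  # low pH is the high-risk side
        assert by_var["cns"]["op"] == "ge"

    def test_root_only_tree_empty(self):
        df = pd.DataFrame({"x": np.arange(50.0), "died": np.zeros(50, int)})
        assert extract_binary_predictors(grow_tree(df, "died", ["x"])) == []

    def test_variable_reused_at_two_cutpoints_two_features(self):
        # die iff x < 2 or x > 8: the tree needs x twice
        x = np.linspace(0, 10, 400)
        df = pd.DataFrame({"x": x, "died": ((x < 2) | (x > 8)).astype(int)})
        tree = grow_tree(df, "died", ["x"], TreeControls(min_split=10))
        preds = extract_binary_predictors(tree)
        assert len({(p["variable"], p["threshold"]) for p in preds}) >= 2


class TestRoundTrip:
    def test_tree_json_round_trip_preserves_predictions(self, planted_tree_frame, tmp_path):
        from calfsid.tree import TreeNode

        res = CartModel(planted_tree_frame, "died", ["ph", "cns", "noise_a"]).fit(seed=0)
        d = res.tree_.to_dict()
        clone = TreeNode.from_dict(d)
        recs = planted_tree_frame.head(100).to_dict("records")
        assert [res.tree_.route(r).predicted_risk for r in recs] == [
            clone.route(r).predicted_risk for r in recs
        ]
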