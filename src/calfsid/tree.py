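"""Classification trees for binary mortality outcomes.

A from-scratch CART implementation with the three behaviours the analysis
depends on and that no single pre-installed Python library combines:

* exhaustive Gini-impurity splitting over every midpoint between distinct
  observed values (3-point ordinal clinical scores are treated as ordered,
  binary flags as 0/1, so every variable reduces to a numeric threshold);
* surrogate splits: at each node, backup rules on other variables ranked
  by how well they agree with the primary split, used to route cases whose
  primary variable is missing (falling back to the majority direction);
* cost-complexity pruning with the subtree chosen at the complexity
  parameter minimizing 10-fold cross-validated misclassification error
  (the *lowest*-error rule, not the 1-SE rule, which is available as an
  option).  Folds are stratified by outcome and reproducible from a seed.

``CartModel(data, outcome, features).fit(seed=...)`` returns a
``CartResults`` carrying the pruned tree, the pruning path, and helpers to
predict and to materialize each split as a named binary risk feature for
downstream logistic modelling.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "TreeControls",
    "SplitRule",
    "TreeNode",
    "PruningPath",
    "CartModel",
    "CartResults",
    "gini_impurity",
    "best_split",
    "find_surrogates",
    "grow_tree",
    "prune_by_cv",
    "extract_binary_predictors",
]


@dataclass(frozen=True)
class TreeControls:
    """Growing controls (rpart-style defaults: grow generously, prune by CV)."""

    min_split: int = 20
    min_bucket: int = 7
    cp: float = 0.001
    max_depth: int = 30
    max_surrogates: int = 5


@dataclass
class SplitRule:
    """``variable < cutpoint`` sends a case left; the cutpoint always lies
    strictly between two observed values.  ``send_left_if_less`` flips the
    orientation for surrogate rules that mimic the primary in reverse."""

    variable: str
    cutpoint: float
    send_left_if_less: bool = True
    agreement: Optional[float] = None  # surrogate agreement with the primary

    def goes_left(self, value: float) -> Optional[bool]:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        less = value < self.cutpoint
        return less if self.send_left_if_less else not less


@dataclass
class TreeNode:
    id: int
    n_survived: int
    n_died: int
    split: Optional[SplitRule] = None
    surrogates: list = field(default_factory=list)
    majority_left: bool = True  # fallback routing when all surrogates missing
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def n(self) -> int:
        return self.n_survived + self.n_died

    @property
    def predicted_risk(self) -> float:
        return self.n_died / self.n

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self):
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    @property
    def misclassified(self) -> int:
        return min(self.n_survived, self.n_died)

    def route(self, record: dict) -> "TreeNode":
        """Descend to a leaf, using surrogates then majority for missing values."""
        node = self
        while not node.is_leaf:
            go_left = node.split.goes_left(record.get(node.split.variable))
            if go_left is None:
                for s in node.surrogates:
                    go_left = s.goes_left(record.get(s.variable))
                    if go_left is not None:
                        break
            if go_left is None:
                go_left = node.majority_left
            node = node.left if go_left else node.right
        return node

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "n_survived": self.n_survived,
            "n_died": self.n_died,
            "predicted_risk": self.predicted_risk,
        }
        if not self.is_leaf:
            d["split"] = {
                "variable": self.split.variable,
                "cutpoint": self.split.cutpoint,
            }
            d["surrogates"] = [
                {
                    "variable": s.variable,
                    "cutpoint": s.cutpoint,
                    "send_left_if_less": s.send_left_if_less,
                    "agreement": s.agreement,
                }
                for s in self.surrogates
            ]
            d["majority_left"] = self.majority_left
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(id=d["id"], n_survived=d["n_survived"], n_died=d["n_died"])
        if "split" in d:
            node.split = SplitRule(d["split"]["variable"], d["split"]["cutpoint"])
            node.surrogates = [
                SplitRule(s["variable"], s["cutpoint"], s["send_left_if_less"], s["agreement"])
                for s in d.get("surrogates", [])
            ]
            node.majority_left = d.get("majority_left", True)
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class PruningPath:
    """Cost-complexity sequence: alpha, subtree size, resubstitution and CV error."""

    alphas: list
    n_leaves: list
    resub_error: list
    cv_error: list
    cv_se: list
    chosen_index: Optional[int] = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "n_leaves": self.n_leaves,
                "resub_error": self.resub_error,
                "cv_error": self.cv_error,
                "cv_se": self.cv_se,
            }
        )


def gini_impurity(counts: Sequence[float]) -> float:
    """Gini index 1 − Σ p_k² of a node's class counts (2p(1−p) for binary)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("counts", "empty node has no impurity")
    p = c / total
    return float(1.0 - np.sum(p * p))


def _count_impurity(n_died: np.ndarray, n_surv: np.ndarray) -> np.ndarray:
    """n * Gini for binary counts: 2·died·survived/n, with 0 for empty."""
    n = n_died + n_surv
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n > 0, 2.0 * n_died * n_surv / np.maximum(n, 1), 0.0)
    return out


def _best_threshold(x: np.ndarray, y: np.ndarray, min_bucket: int):
    """Best Gini-decrease threshold for one numeric feature (NaN excluded).

    Returns (decrease_in_counts, cutpoint) or None.  The decrease is
    measured on the non-missing subset, in count units (n·ΔGini).
    """
    ok = ~np.isnan(x)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2 * min_bucket:
        return None
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    cum_died = np.cumsum(ys)
    total_died = cum_died[-1]
    total_surv = n - total_died
    if total_died == 0 or total_surv == 0:
        return None
    parent = 2.0 * total_died * total_surv / n

    pos = np.flatnonzero(xs[1:] > xs[:-1])  # left block = [0..i]
    if len(pos) == 0:
        return None
    n_left = pos + 1
    valid = (n_left >= min_bucket) & (n - n_left >= min_bucket)
    pos = pos[valid]
    if len(pos) == 0:
        return None
    n_left = pos + 1
    d_left = cum_died[pos]
    s_left = n_left - d_left
    d_right = total_died - d_left
    s_right = (n - n_left) - d_right
    child = _count_impurity(d_left, s_left) + _count_impurity(d_right, s_right)
    decrease = parent - child
    i = int(np.argmax(decrease))  # first max -> smallest cutpoint on ties
    cut = float((xs[pos[i]] + xs[pos[i] + 1]) / 2.0)
    return float(decrease[i]), cut


def best_split(
    X: pd.DataFrame, y: np.ndarray, min_bucket: int = 7
) -> Optional[tuple]:
    """Exhaustive best split over all features and midpoints.

    Returns (SplitRule, gini_decrease_in_counts) for the split maximizing
    the weighted Gini decrease on its non-missing subset, or None when no
    admissible split exists.  Ties break toward the smaller feature index,
    then the smaller cutpoint, so runs are reproducible.
    """
    best = None
    for j, name in enumerate(X.columns):
        res = _best_threshold(X[name].to_numpy(dtype=float), y, min_bucket)
        if res is None:
            continue
        decrease, cut = res
        if best is None or decrease > best[0] + 1e-12:
            best = (decrease, j, cut, name)
    if best is None:
        return None
    return SplitRule(variable=best[3], cutpoint=best[2]), best[0]


def find_surrogates(
    X: pd.DataFrame,
    primary_goes_left: np.ndarray,
    primary_variable: str,
    max_surrogates: int = 5,
) -> list:
    """Backup rules mimicking the primary split's left/right assignment.

    For every other variable the threshold (in either orientation) with
    the highest agreement among cases observed on both variables is found;
    a surrogate is kept only if it beats the majority-direction baseline.
    The list is ordered by decreasing agreement.
    """
    known = ~np.isnan(primary_goes_left)
    gl = primary_goes_left[known].astype(bool)
    n_l, n_r = int(gl.sum()), int((~gl).sum())
    if n_l + n_r == 0:
        return []
    baseline = max(n_l, n_r) / (n_l + n_r)
    out = []
    for name in X.columns:
        if name == primary_variable:
            continue
        x = X[name].to_numpy(dtype=float)[known]
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            continue
        xs_all, gl_all = x[ok], gl[ok]
        order = np.argsort(xs_all, kind="mergesort")
        xs, g = xs_all[order], gl_all[order]
        m = len(xs)
        cum_left = np.cumsum(g)
        tot_left = cum_left[-1]
        tot_right = m - tot_left
        pos = np.flatnonzero(xs[1:] > xs[:-1])
        if len(pos) == 0:
            continue
        size_lo = pos + 1
        l_in_lo = cum_left[pos]
        # orientation 1: value < cut -> left
        agree1 = l_in_lo + (tot_right - (size_lo - l_in_lo))
        # orientation 2: value < cut -> right
        agree2 = (size_lo - l_in_lo) + (tot_left - l_in_lo)
        i1, i2 = int(np.argmax(agree1)), int(np.argmax(agree2))
        if agree1[i1] >= agree2[i2]:
            count, i, send_left = int(agree1[i1]), i1, True
        else:
            count, i, send_left = int(agree2[i2]), i2, False
        agreement = count / (n_l + n_r)  # missing-on-surrogate cases count against it
        if agreement > baseline + 1e-12:
            cut = float((xs[pos[i]] + xs[pos[i] + 1]) / 2.0)
            out.append(SplitRule(name, cut, send_left, agreement=agreement))
    out.sort(key=lambda s: (-s.agreement, s.variable))
    return out[:max_surrogates]


def _route_missing(node: TreeNode, X: pd.DataFrame, idx: np.ndarray, go_left: np.ndarray):
    """Fill NaN routing decisions using surrogates, then the majority direction."""
    missing = np.isnan(go_left)
    for s in node.surrogates:
        if not missing.any():
            break
        xv = X[s.variable].to_numpy(dtype=float)[idx]
        can = missing & ~np.isnan(xv)
        if s.send_left_if_less:
            go_left[can] = (xv[can] < s.cutpoint).astype(float)
        else:
            go_left[can] = (xv[can] >= s.cutpoint).astype(float)
        missing = np.isnan(go_left)
    go_left[missing] = 1.0 if node.majority_left else 0.0
    return go_left.astype(bool)


def grow_tree(
    data: pd.DataFrame,
    outcome: str,
    features: Sequence[str],
    controls: TreeControls = TreeControls(),
) -> TreeNode:
    """Grow a classification tree by recursive Gini splitting.

    The outcome column must be binary 0/1 (1 = died).  Constant features
    are never split on; a split is accepted only if its Gini decrease
    exceeds ``cp`` times the root's total impurity.
    """
    y_all = pd.to_numeric(data[outcome], errors="coerce").to_numpy(dtype=float)
    if np.isnan(y_all).any():
        raise ValidationError(outcome, "outcome contains missing values")
    uniq = np.unique(y_all)
    if not np.isin(uniq, [0.0, 1.0]).all():
        raise ValidationError(outcome, f"outcome is not binary 0/1 (values {uniq[:5]})")
    y_all = y_all.astype(int)
    X = data[list(features)]
    n_root = len(y_all)
    root_count_impurity = _count_impurity(
        np.array(float(y_all.sum())), np.array(float(n_root - y_all.sum()))
    ).item()
    threshold = controls.cp * max(root_count_impurity, 1e-12)

    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y = y_all[idx]
        node = TreeNode(
            id=counter[0], n_survived=int((y == 0).sum()), n_died=int((y == 1).sum())
        )
        counter[0] += 1
        if (
            node.n < controls.min_split
            or node.n_died == 0
            or node.n_survived == 0
            or depth >= controls.max_depth
        ):
            return node
        Xn = X.iloc[idx]
        found = best_split(Xn, y, controls.min_bucket)
        if found is None:
            return node
        rule, decrease = found
        if decrease <= threshold:
            return node
        xv = Xn[rule.variable].to_numpy(dtype=float)
        go_left = np.where(np.isnan(xv), np.nan, (xv < rule.cutpoint).astype(float))
        node.split = rule
        node.surrogates = find_surrogates(
            Xn, go_left, rule.variable, controls.max_surrogates
        )
        obs = ~np.isnan(go_left)
        node.majority_left = bool(np.nansum(go_left[obs]) * 2 >= obs.sum())
        routed_left = _route_missing(node, X, idx, go_left.copy())
        node.left = build(idx[routed_left], depth + 1)
        node.right = build(idx[~routed_left], depth + 1)
        return node

    return build(np.arange(n_root), 0)


# ---------------------------------------------------------------------------
# cost-complexity pruning
# ---------------------------------------------------------------------------


def _subtree_stats(node: TreeNode):
    leaves = node.leaves()
    return sum(l.misclassified for l in leaves), len(leaves)


def _make_leaf(node: TreeNode) -> None:
    node.split = None
    node.surrogates = []
    node.left = None
    node.right = None


def _weakest_links(tree: TreeNode):
    """(g, node) for each internal node: g = (R(t) − R(T_t)) / (|leaves|−1)."""
    out = []
    for node in tree.internal_nodes():
        r_sub, n_leaves = _subtree_stats(node)
        g = (node.misclassified - r_sub) / (n_leaves - 1)
        out.append((g, node))
    return out


def cost_complexity_sequence(tree: TreeNode):
    """Nested subtree sequence of weakest-link pruning.

    Returns (alphas, subtrees): alphas strictly increasing starting at 0,
    subtrees[k] optimal for alpha in [alphas[k], alphas[k+1]).
    """
    t = copy.deepcopy(tree)
    alphas = [0.0]
    subtrees = [copy.deepcopy(t)]
    while not t.is_leaf:
        links = _weakest_links(t)
        gmin = min(g for g, _ in links)
        for g, node in links:
            if g <= gmin + 1e-12 and not node.is_leaf:
                _make_leaf(node)
        if gmin <= alphas[-1] + 1e-12:
            subtrees[-1] = copy.deepcopy(t)  # merge ties: keep the smaller tree
        else:
            alphas.append(gmin)
            subtrees.append(copy.deepcopy(t))
    return alphas, subtrees


def prune_at_alpha(tree: TreeNode, alpha: float) -> TreeNode:
    """Smallest optimal subtree for complexity penalty ``alpha``."""
    t = copy.deepcopy(tree)
    while not t.is_leaf:
        links = _weakest_links(t)
        gmin = min(g for g, _ in links)
        if gmin > alpha + 1e-12:
            break
        for g, node in links:
            if g <= gmin + 1e-12 and not node.is_leaf:
                _make_leaf(node)
    return t


def _predict_died(tree: TreeNode, data: pd.DataFrame) -> np.ndarray:
    records = data.to_dict("records")
    return np.array([1 if tree.route(r).predicted_risk >= 0.5 else 0 for r in records])


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def prune_by_cv(
    tree: TreeNode,
    data: pd.DataFrame,
    outcome: str,
    features: Sequence[str],
    controls: TreeControls = TreeControls(),
    folds: int = 10,
    seed: int = 0,
    one_se: bool = False,
):
    """Select the subtree at the alpha with lowest cross-validated error.

    10-fold CV, stratified by outcome, reproducible from ``seed``: for each
    representative alpha (geometric mean of consecutive path alphas) every
    fold's tree is grown on the training part, pruned at that alpha, and
    scored on the held-out part by misclassification.  Ties in CV error go
    to the larger alpha (the smaller subtree).  ``one_se=True`` applies
    the optional 1-SE rule instead of the minimum.
    """
    y = pd.to_numeric(data[outcome], errors="coerce").to_numpy(dtype=float).astype(int)
    n = len(y)
    if n < folds:
        raise ValidationError("data", f"fewer cases ({n}) than folds ({folds})")
    alphas, subtrees = cost_complexity_sequence(tree)
    k = len(alphas)
    betas = [
        math.sqrt(alphas[i] * alphas[i + 1]) if i + 1 < k else alphas[i]
        for i in range(k)
    ]

    fold_of = _stratified_folds(y, folds, seed)
    errors = np.zeros(k)
    if k > 1:
        for f in range(folds):
            train = data[fold_of != f]
            test = data[fold_of == f]
            y_test = y[fold_of == f]
            fold_tree = grow_tree(train, outcome, features, controls)
            for i, beta in enumerate(betas):
                pred = _predict_died(prune_at_alpha(fold_tree, beta), test)
                errors[i] += int((pred != y_test).sum())
    cv_err = errors / n
    cv_se = np.sqrt(np.maximum(cv_err * (1 - cv_err), 0.0) / n)
    resub = np.array([_subtree_stats(t)[0] / n for t in subtrees])
    sizes = [len(t.leaves()) for t in subtrees]

    if k == 1:
        chosen = 0
    else:
        best_err = cv_err.min()
        candidates = np.flatnonzero(cv_err <= best_err + 1e-12)
        if one_se:
            limit = best_err + cv_se[candidates[-1]]
            candidates = np.flatnonzero(cv_err <= limit + 1e-12)
        chosen = int(candidates[-1])  # largest alpha among ties -> smallest tree

    path = PruningPath(
        alphas=list(alphas),
        n_leaves=sizes,
        resub_error=list(resub),
        cv_error=list(cv_err),
        cv_se=list(cv_se),
        chosen_index=chosen,
    )
    return copy.deepcopy(subtrees[chosen]), path


def extract_binary_predictors(tree: TreeNode) -> list[dict]:
    """One binary risk feature per distinct split, TRUE = higher-risk side.

    Each entry has ``name`` ("ph < 6.85"), ``variable``, ``op`` (lt/ge) and
    ``threshold``; the orientation is chosen so the indicator is 1 on the
    child with the higher death risk.  A variable reused at two cutpoints
    yields two distinct features.
    """
    out = []
    seen = set()
    for node in tree.internal_nodes():
        rule = node.split
        right_riskier = node.right.predicted_risk >= node.left.predicted_risk
        op = "ge" if right_riskier else "lt"
        key = (rule.variable, rule.cutpoint, op)
        if key in seen:
            continue
        seen.add(key)
        sym = ">=" if op == "ge" else "<"
        out.append(
            {
                "name": f"{rule.variable} {sym} {rule.cutpoint:g}",
                "variable": rule.variable,
                "op": op,
                "threshold": rule.cutpoint,
            }
        )
    return out


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class CartModel:
    """Classification-tree model built from a cohort dataframe.

    ``fit()`` grows the tree with the configured controls and (by default)
    prunes it by 10-fold cross-validation, returning a ``CartResults``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        features: Sequence[str],
        controls: TreeControls = TreeControls(),
    ):
        missing_cols = [c for c in [outcome, *features] if c not in data.columns]
        if missing_cols:
            raise ValidationError("data", f"missing columns: {missing_cols}")
        self.data = data
        self.outcome = outcome
        self.features = list(features)
        self.controls = controls

    @classmethod
    def from_dataframe(cls, data, outcome, features, **kw):
        return cls(data, outcome, features, **kw)

    def fit(self, seed: int = 0, prune: bool = True, folds: int = 10, one_se: bool = False):
        full = grow_tree(self.data, self.outcome, self.features, self.controls)
        if prune and not full.is_leaf:
            pruned, path = prune_by_cv(
                full,
                self.data,
                self.outcome,
                self.features,
                self.controls,
                folds=folds,
                seed=seed,
                one_se=one_se,
            )
        else:
            pruned = full
            n = max(full.n, 1)
            path = PruningPath(
                alphas=[0.0],
                n_leaves=[len(full.leaves())],
                resub_error=[_subtree_stats(full)[0] / n],
                cv_error=[float("nan")],
                cv_se=[float("nan")],
                chosen_index=0,
            )
        return CartResults(self, full_tree=full, tree=pruned, pruning_path=path, seed=seed)


class CartResults:
    """Fitted (grown + pruned) classification tree."""

    def __init__(self, model: CartModel, full_tree: TreeNode, tree: TreeNode, pruning_path: PruningPath, seed: int):
        self.model = model
        self.full_tree_ = full_tree
        self.tree_ = tree
        self.pruning_path_ = pruning_path
        self.seed = seed

    def predict_risk(self, data: pd.DataFrame) -> np.ndarray:
        return np.array([self.tree_.route(r).predicted_risk for r in data.to_dict("records")])

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return (self.predict_risk(data) >= 0.5).astype(int)

    def extract_binary_predictors(self) -> list[dict]:
        return extract_binary_predictors(self.tree_)

    def flat_table(self) -> pd.DataFrame:
        """Rendering-friendly one-row-per-node table."""
        rows = []

        def walk(node, depth, side):
            rows.append(
                {
                    "id": node.id,
                    "depth": depth,
                    "side": side,
                    "split": node.split.variable if node.split else "<leaf>",
                    "cutpoint": node.split.cutpoint if node.split else float("nan"),
                    "n": node.n,
                    "died": node.n_died,
                    "risk": node.predicted_risk,
                }
            )
            if not node.is_leaf:
                walk(node.left, depth + 1, "L")
                walk(node.right, depth + 1, "R")

        walk(self.tree_, 0, "-")
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Classification tree: {len(self.tree_.leaves())} leaves "
            f"(grown {len(self.full_tree_.leaves())}), n = {self.tree_.n}, "
            f"CV seed = {self.seed}",
        ]

        def walk(node, indent):
            if node.is_leaf:
                lines.append(
                    f"{indent}leaf: n={node.n} died={node.n_died} risk={node.predicted_risk:.3f}"
                )
                return
            lines.append(
                f"{indent}{node.split.variable} < {node.split.cutpoint:g} "
                f"[n={node.n}, risk={node.predicted_risk:.3f}, "
                f"{len(node.surrogates)} surrogate(s)]"
            )
            walk(node.left, indent + "  ")
            walk(node.right, indent + "  ")

        walk(self.tree_, "")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tree": self.tree_.to_dict(),
                    "pruning_path": self.pruning_path_.as_frame().to_dict("list"),
                    "seed": self.seed,
                    "controls": vars(self.model.controls),
                },
                fh,
                indent=2,
            )
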