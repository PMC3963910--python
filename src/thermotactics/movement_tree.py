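"""Excursion frequencies, travelled distances, and the threshold tree.

The rate at which a fish visits the epilimnion (percent of its daily fixes
classed as epilimnetic) is modelled by a least-squares binary regression
tree on daily lake covariates (mean epilimnion and metalimnion temperature,
day of year, year).  Three methodological refinements matter for clustered
telemetry data and are implemented here rather than delegated:

* **unit-blocked cross-validation** — folds contain whole sampling units
  (fish), so repeated, correlated measures of one fish never sit on both
  sides of a train/validation split;
* **1-SE pruning** — the smallest subtree whose cross-validated error is
  within one standard error of the minimum;
* **a unit-block permutation test** — whole response blocks are reshuffled
  among units of equal size and a tree of equal complexity refit, asking
  whether the observed tree explains more variance than chance trees.

Split search is exhaustive: every midpoint between consecutive distinct
predictor values is scored by its sum-of-squares reduction, with ties broken
by column order and then by the smaller threshold, so the grown tree is
reproducible and checkable against a brute-force search.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import (
    AmbiguousOrderError,
    DegenerateInputError,
    InvalidRequestError,
)

__all__ = [
    "TreeNode",
    "TreeModel",
    "CVResult",
    "PermutationResult",
    "excursion_frequency",
    "travelled_distances",
    "grow_tree",
    "grouped_cv",
    "prune_1se",
    "select_size_1se",
    "permutation_test",
    "summarize_movement",
    "GroupedRegressionTree",
]

PERIODS = ("dawn", "day", "dusk", "night")


# ---------------------------------------------------------------------------
# telemetry-derived quantities


def excursion_frequency(fixes: pd.DataFrame, layers: pd.DataFrame) -> pd.DataFrame:
    """Daily epilimnion-excursion percentage per fish, joined to lake covariates.

    ``fixes`` needs columns ``fish_id``, ``timestamp`` and ``in_epilimnion``
    (boolean; NaN where occupancy was undefined, e.g. unstratified hours).
    ``layers`` is the daily layer table with ``date``, ``epi_mean`` and
    ``meta_mean``.  Fish-days with no defined fix, or days missing from the
    layer table, are dropped with a warning.
    """
    df = fixes.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    lay = layers.copy()
    lay["date"] = pd.to_datetime(lay["date"])
    lay = lay.set_index("date")
    records = []
    for (fish, date), grp in df.groupby(["fish_id", "date"], sort=True):
        occ = grp["in_epilimnion"]
        defined = occ.notna()
        if defined.sum() == 0:
            warnings.warn(f"fish {fish} on {date.date()}: no fix with defined "
                          "occupancy; day dropped", stacklevel=2)
            continue
        if date not in lay.index:
            warnings.warn(f"{date.date()}: no layer summary; fish {fish} day dropped",
                          stacklevel=2)
            continue
        pct = 100.0 * occ[defined].astype(bool).sum() / defined.sum()
        records.append({
            "fish_id": fish,
            "date": date,
            "excursion_pct": float(pct),
            "epi_mean": float(lay.loc[date, "epi_mean"]),
            "meta_mean": float(lay.loc[date, "meta_mean"]),
            "day_of_year": int(date.dayofyear),
            "year": int(date.year),
        })
    return pd.DataFrame(records)


def travelled_distances(fixes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Straight-line step distances between consecutive fixes, per fish.

    Returns ``(steps, daily)``: each step is labelled with its arrival
    timestamp and period; the daily table sums the steps arriving on each
    fish-date.  Duplicate timestamps within one fish make the order
    ambiguous and raise.
    """
    df = fixes.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    steps = []
    for fish, grp in df.groupby("fish_id", sort=True):
        grp = grp.sort_values("timestamp")
        if grp["timestamp"].duplicated().any():
            raise AmbiguousOrderError(f"fish {fish}: duplicate fix timestamps")
        de = grp["easting"].diff().to_numpy()
        dn = grp["northing"].diff().to_numpy()
        dist = np.hypot(de, dn)
        arr = grp.iloc[1:]
        for i, (_, row) in enumerate(arr.iterrows(), start=1):
            steps.append({
                "fish_id": fish,
                "timestamp": row["timestamp"],
                "date": row["timestamp"].normalize(),
                "period": row.get("period", None),
                "distance": float(dist[i]),
            })
    steps_df = pd.DataFrame(steps, columns=["fish_id", "timestamp", "date",
                                            "period", "distance"])
    if steps_df.empty:
        daily = pd.DataFrame(columns=["fish_id", "date", "total_distance"])
    else:
        daily = (steps_df.groupby(["fish_id", "date"], as_index=False)["distance"]
                 .sum().rename(columns={"distance": "total_distance"}))
    return steps_df, daily


def summarize_movement(steps: pd.DataFrame, condition) -> pd.DataFrame:
    """Mean, SD and count of step distance per (period x thermal condition).

    ``condition`` is aligned with ``steps`` and holds ``"below"``/``"above"``
    labels (or booleans, True meaning above the threshold).  Empty cells are
    reported with ``n = 0`` and an undefined (NaN) mean.
    """
    cond = pd.Series(list(condition), index=steps.index)
    if cond.dtype == bool or set(cond.unique()) <= {True, False}:
        cond = cond.map({True: "above", False: "below"})
    rows = []
    for period in PERIODS:
        for c in ("below", "above"):
            sel = steps[(steps["period"] == period) & (cond == c)]["distance"]
            rows.append({
                "period": period,
                "condition": c,
                "mean": float(sel.mean()) if len(sel) else np.nan,
                "sd": float(sel.std(ddof=1)) if len(sel) > 1 else
                      (0.0 if len(sel) == 1 else np.nan),
                "n": int(len(sel)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression tree


@dataclass
class TreeNode:
    n: int
    sse: float
    mean: float
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaf_stats(self) -> tuple[float, int]:
        """(total SSE over leaves, number of leaves) of this subtree."""
        if self.is_leaf:
            return self.sse, 1
        ls, ln = self.left.leaf_stats()
        rs, rn = self.right.leaf_stats()
        return ls + rs, ln + rn

    def copy(self) -> "TreeNode":
        return TreeNode(self.n, self.sse, self.mean, self.feature, self.threshold,
                        self.left.copy() if self.left else None,
                        self.right.copy() if self.right else None)


def _node_sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _exact_reduction(X: np.ndarray, y: np.ndarray, sse_node: float,
                     f: int, t: float) -> float:
    """Split reduction scored exactly as a direct brute force would."""
    mask = X[:, f] <= t
    yl = y[mask]
    yr = y[~mask]
    return sse_node - (np.sum((yl - yl.mean()) ** 2)
                       + np.sum((yr - yr.mean()) ** 2))


def _best_split(X: np.ndarray, y: np.ndarray, sse_node: float, min_leaf: int):
    """Exhaustive best split of one node.

    Candidates are midpoints between consecutive distinct values of each
    predictor; the winner maximizes the SSE reduction.  Ties go to the
    first predictor in column order, then to the smallest threshold.
    Returns ``(reduction, feature, threshold)`` or ``None``.

    A fast prefix-sum scan shortlists the candidates within a small margin
    of the maximum; those few are then re-scored with the direct SSE
    computation, so near-ties are resolved identically to a naive
    exhaustive search, free of prefix-sum round-off.
    """
    n = y.size
    shortlist: list[tuple[int, float]] = []       # (feature, threshold)
    red_max = -np.inf
    per_feature: list[tuple[int, np.ndarray, np.ndarray]] = []
    for f in range(X.shape[1]):
        xf = X[:, f]
        order = np.argsort(xf, kind="stable")
        xs = xf[order]
        ys = y[order]
        c1 = np.cumsum(ys)
        c2 = np.cumsum(ys * ys)
        nl = np.arange(1, n)
        nr = n - nl
        sse_l = c2[:-1] - c1[:-1] ** 2 / nl
        sse_r = (c2[-1] - c2[:-1]) - (c1[-1] - c1[:-1]) ** 2 / nr
        red = sse_node - sse_l - sse_r
        valid = (xs[1:] > xs[:-1]) & (nl >= min_leaf) & (nr >= min_leaf)
        if not valid.any():
            continue
        red = np.where(valid, red, -np.inf)
        per_feature.append((f, xs, red))
        red_max = max(red_max, float(red.max()))
    if not per_feature:
        return None
    eps = 1e-9 * max(abs(sse_node), 1.0)
    for f, xs, red in per_feature:
        for i in np.where(red >= red_max - eps)[0]:
            shortlist.append((f, float(0.5 * (xs[i] + xs[i + 1]))))
    best = None
    for f, t in shortlist:                         # (feature, threshold) order
        r = float(_exact_reduction(X, y, sse_node, f, t))
        if best is None or r > best[0]:
            best = (r, f, t)
    return best


def _grow(X: np.ndarray, y: np.ndarray, min_leaf: int, cp: float,
          sse_root: float) -> TreeNode:
    node = TreeNode(n=y.size, sse=_node_sse(y), mean=float(y.mean()))
    if y.size < 2 * min_leaf or node.sse <= 0:
        return node
    best = _best_split(X, y, node.sse, min_leaf)
    if best is None or (sse_root > 0 and best[0] / sse_root < cp):
        return node
    _, f, t = best
    mask = X[:, f] <= t
    node.feature, node.threshold = f, t
    node.left = _grow(X[mask], y[mask], min_leaf, cp, sse_root)
    node.right = _grow(X[~mask], y[~mask], min_leaf, cp, sse_root)
    return node


def _grow_best_first(X: np.ndarray, y: np.ndarray, min_leaf: int,
                     max_leaves: int) -> TreeNode:
    """Greedy growth splitting the globally best leaf until ``max_leaves``.

    Used to build null trees of fixed complexity for the permutation test;
    with ``max_leaves = 2`` it reduces to the plain root split.
    """
    idx_all = np.arange(y.size)
    root = TreeNode(n=y.size, sse=_node_sse(y), mean=float(y.mean()))
    heap: list = []
    counter = 0

    def push(node: TreeNode, idx: np.ndarray) -> None:
        nonlocal counter
        if idx.size < 2 * min_leaf or node.sse <= 0:
            return
        best = _best_split(X[idx], y[idx], node.sse, min_leaf)
        if best is None or best[0] <= 0:
            return
        heapq.heappush(heap, (-best[0], best[1], best[2], counter, node, idx))
        counter += 1

    push(root, idx_all)
    leaves = 1
    while heap and leaves < max_leaves:
        _, f, t, _, node, idx = heapq.heappop(heap)
        mask = X[idx, f] <= t
        node.feature, node.threshold = f, t
        node.left = TreeNode(n=int(mask.sum()), sse=_node_sse(y[idx[mask]]),
                             mean=float(y[idx[mask]].mean()))
        node.right = TreeNode(n=int((~mask).sum()), sse=_node_sse(y[idx[~mask]]),
                              mean=float(y[idx[~mask]].mean()))
        leaves += 1
        if leaves < max_leaves:
            push(node.left, idx[mask])
            push(node.right, idx[~mask])
    return root


def _pruned(node: TreeNode, alpha: float) -> TreeNode:
    """Optimal cost-complexity pruning at penalty ``alpha`` (bottom-up)."""
    if node.is_leaf:
        return TreeNode(node.n, node.sse, node.mean)
    left = _pruned(node.left, alpha)
    right = _pruned(node.right, alpha)
    leaf_sse, leaves = (lambda a, b: (a[0] + b[0], a[1] + b[1]))(
        left.leaf_stats(), right.leaf_stats())
    g = (node.sse - leaf_sse) / (leaves - 1)
    if g <= alpha * (1 + 1e-12) + 1e-12:
        return TreeNode(node.n, node.sse, node.mean)
    return TreeNode(node.n, node.sse, node.mean, node.feature, node.threshold,
                    left, right)


def _min_g(node: TreeNode) -> float:
    """Smallest weakest-link penalty over internal nodes."""
    if node.is_leaf:
        return np.inf
    leaf_sse, leaves = node.leaf_stats()
    g = (node.sse - leaf_sse) / (leaves - 1)
    return min(g, _min_g(node.left), _min_g(node.right))


@dataclass
class TreeModel:
    """A fitted regression tree with its cost-complexity subtree sequence."""

    root: TreeNode
    feature_names: tuple[str, ...]
    sse_root: float
    n: int
    min_leaf: int
    cp: float
    subtrees: tuple[tuple[float, int, float, TreeNode], ...] = field(default=())
    # each entry: (alpha, n_leaves, relative training error, pruned root)

    @property
    def leaf_count(self) -> int:
        return self.root.leaf_stats()[1]

    @property
    def r2(self) -> float:
        if self.sse_root <= 0:
            return 0.0
        return 1.0 - self.root.leaf_stats()[0] / self.sse_root

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            node = self.root
            while not node.is_leaf:
                node = node.left if X[i, node.feature] <= node.threshold else node.right
            out[i] = node.mean
        return out

    def splits(self) -> list[dict]:
        """Depth-first list of split records (variable, value, SSE drop)."""
        recs = []

        def walk(node: TreeNode, depth: int) -> None:
            if node.is_leaf:
                return
            drop = node.sse - node.left.sse - node.right.sse
            recs.append({
                "variable": self.feature_names[node.feature],
                "value": node.threshold,
                "n": node.n,
                "sse_drop": drop,
                "r2_share": drop / self.sse_root if self.sse_root > 0 else 0.0,
                "depth": depth,
            })
            walk(node.left, depth + 1)
            walk(node.right, depth + 1)

        walk(self.root, 0)
        return recs

    def leaves(self) -> list[dict]:
        recs = []

        def walk(node: TreeNode, path: str) -> None:
            if node.is_leaf:
                recs.append({"mean": node.mean, "n": node.n, "path": path})
                return
            name = self.feature_names[node.feature]
            walk(node.left, f"{path}{name} <= {node.threshold:g}; ")
            walk(node.right, f"{path}{name} > {node.threshold:g}; ")

        walk(self.root, "")
        return recs

    def pruned_to(self, n_leaves: int) -> "TreeModel":
        """The subtree in the cost-complexity sequence with ``n_leaves``
        leaves (or the largest one not exceeding it)."""
        cands = [s for s in self.subtrees if s[1] <= n_leaves]
        alpha, nl, rel, rootp = max(cands, key=lambda s: s[1])
        return TreeModel(rootp.copy(), self.feature_names, self.sse_root, self.n,
                         self.min_leaf, self.cp, self.subtrees)


def _as_matrix(X, feature_names=None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names:
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float).reshape(len(X), -1)


def _feature_names(X, p: int) -> tuple[str, ...]:
    if isinstance(X, pd.DataFrame):
        return tuple(map(str, X.columns))
    return tuple(f"x{j}" for j in range(p))


def _subtree_sequence(root: TreeNode, sse_root: float):
    seq = []
    cur = root.copy()
    alpha = 0.0
    while True:
        leaf_sse, leaves = cur.leaf_stats()
        rel = leaf_sse / sse_root if sse_root > 0 else 1.0
        seq.append((alpha, leaves, rel, cur))
        if cur.is_leaf:
            break
        alpha = _min_g(cur)
        cur = _pruned(cur, alpha)
    return tuple(seq)


def grow_tree(X, y, min_leaf: int = 5, cp: float = 0.01,
              max_leaves: int | None = None) -> TreeModel:
    """Grow a least-squares regression tree by exhaustive binary splitting.

    Splitting stops when a child would fall below ``min_leaf`` observations
    or the best split's SSE reduction, relative to the root SSE, drops below
    ``cp``.  A constant response yields a single leaf.  The returned model
    carries its full weakest-link subtree sequence for pruning.

    With ``max_leaves`` set, the tree is instead grown best-first (always
    splitting the leaf with the largest SSE reduction) to exactly that many
    leaves where achievable — the fixed-complexity fits used by the
    permutation test.
    """
    y = np.asarray(y, dtype=float)
    names = _feature_names(X, _as_matrix(X).shape[1])
    Xm = _as_matrix(X)
    if min_leaf < 1:
        raise InvalidRequestError("min_leaf must be >= 1")
    if y.size < 2 * min_leaf:
        raise InvalidRequestError("need at least 2*min_leaf observations")
    sse_root = _node_sse(y)
    if max_leaves is not None:
        root = _grow_best_first(Xm, y, min_leaf, max_leaves)
    else:
        root = _grow(Xm, y, min_leaf, cp, sse_root)
    model = TreeModel(root, names, sse_root, y.size, min_leaf, cp)
    model.subtrees = _subtree_sequence(root, sse_root)
    return model


@dataclass
class CVResult:
    """Cross-validated error per candidate complexity.

    ``table`` columns: ``alpha`` (pruning penalty), ``n_leaves`` (on the
    tree fitted to all data), ``rel_error`` (training), ``cv_error`` and
    ``cv_se`` — errors are relative to the root SSE of the full response.
    """

    table: pd.DataFrame
    fold_of: dict
    n_folds: int
    seed: int | None


def grouped_cv(X, y, units, n_folds: int = 10, seed: int | None = None,
               tree: TreeModel | None = None, min_leaf: int = 5,
               cp: float = 0.01) -> CVResult:
    """Cross-validation over whole sampling units.

    Unit labels are shuffled with ``seed`` and dealt round-robin into
    ``n_folds`` folds, so every observation of a unit shares its fold and
    held-out units are predicted only from other units.  For each candidate
    penalty in the full tree's subtree sequence (geometric means of adjacent
    critical alphas), trees grown on the training folds are pruned at that
    penalty and scored on the held-out units.
    """
    y = np.asarray(y, dtype=float)
    Xm = _as_matrix(X)
    units = np.asarray(units)
    uniq = np.unique(units)
    if n_folds > uniq.size:
        raise InvalidRequestError(
            f"{n_folds} folds requested but only {uniq.size} sampling units")
    if tree is None:
        tree = grow_tree(X, y, min_leaf=min_leaf, cp=cp)
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    fold_of = {uniq[j]: i % n_folds for i, j in enumerate(order)}
    fold_idx = np.array([fold_of[u] for u in units])

    alphas = [s[0] for s in tree.subtrees]
    cands = [float(np.sqrt(alphas[k] * alphas[k + 1])) for k in range(len(alphas) - 1)]
    cands.append(alphas[-1] if alphas[-1] > 0 else 0.0)

    sse_root_total = _node_sse(y)
    n_c = len(cands)
    fold_err = np.zeros((n_folds, n_c))
    for f in range(n_folds):
        tr = fold_idx != f
        te = ~tr
        sub = grow_tree(Xm[tr], y[tr], min_leaf=tree.min_leaf, cp=tree.cp)
        scale = sub.sse_root / sse_root_total if sse_root_total > 0 else 1.0
        for c, a in enumerate(cands):
            proot = _pruned(sub.root, a * scale)
            pm = TreeModel(proot, sub.feature_names, sub.sse_root, int(tr.sum()),
                           tree.min_leaf, tree.cp)
            pred = pm.predict(Xm[te])
            sse = float(np.sum((y[te] - pred) ** 2))
            fold_err[f, c] = sse / sse_root_total * n_folds
    cv_error = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    table = pd.DataFrame({
        "alpha": [s[0] for s in tree.subtrees],
        "cand_alpha": cands,
        "n_leaves": [s[1] for s in tree.subtrees],
        "rel_error": [s[2] for s in tree.subtrees],
        "cv_error": cv_error,
        "cv_se": cv_se,
    })
    return CVResult(table=table, fold_of=fold_of, n_folds=n_folds, seed=seed)


def select_size_1se(n_leaves, cv_error, cv_se) -> int:
    """Index of the smallest tree within one SE of the minimum CV error."""
    n_leaves = np.asarray(n_leaves)
    cv_error = np.asarray(cv_error, dtype=float)
    cv_se = np.asarray(cv_se, dtype=float)
    i_min = int(np.argmin(cv_error))
    thr = cv_error[i_min] + cv_se[i_min]
    ok = np.where(cv_error <= thr + 1e-12)[0]
    return int(ok[np.argmin(n_leaves[ok])])


def prune_1se(tree: TreeModel, cv: CVResult) -> TreeModel:
    """Prune to the smallest subtree within one SE of the CV-error minimum."""
    i = select_size_1se(cv.table["n_leaves"], cv.table["cv_error"], cv.table["cv_se"])
    target = int(cv.table["n_leaves"].iloc[i])
    return tree.pruned_to(target)


@dataclass
class PermutationResult:
    observed_r2: float
    null_r2: np.ndarray
    p_value: float
    m: int


def permutation_test(pruned: TreeModel, X, y, units, m: int = 999,
                     seed: int | None = None) -> PermutationResult:
    """Unit-block permutation test of the pruned tree's explained variance.

    Whole response blocks are reshuffled among sampling units of equal size
    (within-unit correlation is preserved under the null), a tree of the
    observed leaf count is grown greedily on each permuted response, and
    ``p = (#{null r2 >= observed} + 1) / (m + 1)``.
    """
    y = np.asarray(y, dtype=float)
    Xm = _as_matrix(X, pruned.feature_names) if isinstance(X, pd.DataFrame) \
        else _as_matrix(X)
    units = np.asarray(units)
    if m < 99:
        raise InvalidRequestError("use at least 99 permutations")
    if pruned.leaf_count < 2:
        raise InvalidRequestError("permutation test needs a tree with >= 2 leaves")
    if _node_sse(y) <= 0:
        raise DegenerateInputError("constant response: test undefined")
    L = pruned.leaf_count
    observed = pruned.r2
    rng = np.random.default_rng(seed)

    uniq, counts = np.unique(units, return_counts=True)
    rows_of = {u: np.where(units == u)[0] for u in uniq}
    by_size: dict[int, list] = {}
    for u, c in zip(uniq, counts):
        by_size.setdefault(int(c), []).append(u)

    sse_root = _node_sse(y)
    null = np.empty(m)
    for b in range(m):
        y_perm = np.empty_like(y)
        for size, members in by_size.items():
            perm = rng.permutation(len(members))
            for i, u in enumerate(members):
                y_perm[rows_of[u]] = y[rows_of[members[perm[i]]]]
        root = _grow_best_first(Xm, y_perm, pruned.min_leaf, L)
        leaf_sse, _ = root.leaf_stats()
        null[b] = 1.0 - leaf_sse / sse_root
    p = (float(np.sum(null >= observed)) + 1.0) / (m + 1.0)
    return PermutationResult(observed_r2=observed, null_r2=null, p_value=p, m=m)


class GroupedRegressionTree(BaseEstimator, RegressorMixin):
    """CART regression tree with unit-blocked CV and 1-SE pruning.

    Parameters
    ----------
    min_leaf : int, default 5
        Minimum observations in each child of a split.
    cp : float, default 0.01
        Complexity parameter: minimum SSE reduction of a split relative to
        the root SSE.
    n_folds : int, default 10
        Folds for the unit-blocked cross-validation.
    prune : {"1se", "none"}, default "1se"
    random_state : int or None
        Seed for the fold assignment.

    ``fit(X, y, groups=...)`` requires the per-observation sampling-unit
    labels (fish ids).  Fitted attributes: ``tree_`` (pruned),
    ``full_tree_``, ``cv_result_``, ``r2_``, ``leaf_count_``.
    """

    def __init__(self, min_leaf: int = 5, cp: float = 0.01, n_folds: int = 10,
                 prune: str = "1se", random_state: int | None = None):
        self.min_leaf = min_leaf
        self.cp = cp
        self.n_folds = n_folds
        self.prune = prune
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        if groups is None:
            raise InvalidRequestError("groups (sampling-unit labels) are required")
        y = np.asarray(y, dtype=float)
        self.full_tree_ = grow_tree(X, y, min_leaf=self.min_leaf, cp=self.cp)
        if self.prune == "1se":
            self.cv_result_ = grouped_cv(X, y, groups, n_folds=self.n_folds,
                                         seed=self.random_state, tree=self.full_tree_)
            self.tree_ = prune_1se(self.full_tree_, self.cv_result_)
        else:
            self.cv_result_ = None
            self.tree_ = self.full_tree_
        self.r2_ = self.tree_.r2
        self.leaf_count_ = self.tree_.leaf_count
        self.feature_names_in_ = np.asarray(self.full_tree_.feature_names)
        self.n_features_in_ = len(self.full_tree_.feature_names)
        self._fit_data = (X, y, np.asarray(groups))
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return self.tree_.predict(X)

    def permutation_test(self, m: int = 999,
                         random_state: int | None = None) -> PermutationResult:
        check_is_fitted(self, "tree_")
        X, y, groups = self._fit_data
        return permutation_test(self.tree_, X, y, groups, m=m, seed=random_state)
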