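"""Model interpreters: TreeSHAP, accumulated local effects, surrogate tree.

* :func:`tree_shap` computes exact path-dependent Shapley values per
  tree: the value function of a feature subset S follows the data at
  nodes splitting on features in S and takes the cover-weighted average
  of both children elsewhere.  Because a depth-limited tree uses only a
  handful of features, the exact Shapley sum over subsets of the tree's
  own features is cheap, and features absent from a tree are dummy
  players with zero attribution.  Tree values are summed over the
  ensemble and scaled by the learning rate, so additivity
  ``base + sum(phi) == prediction`` holds to machine precision.
* :func:`ale_profile` estimates the centered accumulated-local-effects
  main effect of one predictor over quantile bins.
* :class:`SurrogateTree` distills the boosted model into at most five
  split criteria by permutation-test split selection (a simplified
  conditional-inference criterion with a Bonferroni-style multiplicity
  adjustment), reporting fidelity as R^2 against the full model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._base import BaseEstimator
from .boosting import GradientBoostedTreeRegressor, RegressionTree, _best_split

__all__ = [
    "ShapMatrix",
    "tree_shap",
    "shap_importance",
    "AleProfile",
    "ale_profile",
    "ale_profiles",
    "ale_importance",
    "SurrogateTree",
]


@dataclass
class ShapMatrix:
    """Per-sample additive contributions (target units) and base value."""

    values: np.ndarray          # n_samples x n_predictors
    base_value: float
    feature_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or [f"x{j}" for j in range(self.values.shape[1])]
        return pd.DataFrame(self.values, columns=cols)


def _tree_expectation(tree: RegressionTree, x: np.ndarray, in_subset: np.ndarray) -> float:
    """Cover-weighted conditional expectation of one tree.

    Features flagged in ``in_subset`` follow the sample; the rest are
    marginalized over the training cover distribution.
    """

    def rec(node: int) -> float:
        f = tree.feature[node]
        if f < 0:
            return tree.value[node]
        if in_subset[f]:
            child = tree.left[node] if x[f] < tree.threshold[node] else tree.right[node]
            return rec(child)
        l, r = tree.left[node], tree.right[node]
        cl, cr = tree.cover[l], tree.cover[r]
        return (cl * rec(l) + cr * rec(r)) / (cl + cr)

    return rec(0)


def _shap_one_tree(tree: RegressionTree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values of the path-dependent value function."""
    used = tree.features_used()
    phi = np.zeros(n_features)
    if not used:
        return phi
    d = len(used)
    in_subset = np.zeros(n_features, dtype=bool)
    # value of every subset of the tree's features
    values = {}
    for mask in range(1 << d):
        in_subset[:] = False
        for i in range(d):
            if mask >> i & 1:
                in_subset[used[i]] = True
        values[mask] = _tree_expectation(tree, x, in_subset)
    fact = [math.factorial(i) for i in range(d + 1)]
    for i, f in enumerate(used):
        for mask in range(1 << d):
            if mask >> i & 1:
                continue
            s = bin(mask).count("1")
            weight = fact[s] * fact[d - s - 1] / fact[d]
            phi[f] += weight * (values[mask | (1 << i)] - values[mask])
    return phi


def tree_shap(model: GradientBoostedTreeRegressor, X) -> ShapMatrix:
    """Path-dependent TreeSHAP of a boosted ensemble.

    Returns contributions in target units (MJ/d for REI models); the
    base value is the cover-weighted expected prediction.
    """
    model._check_fitted("trees_")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("samples contain non-finite features")
    n, p = X.shape
    phi = np.zeros((n, p))
    base = model.base_score_
    none = np.zeros(p, dtype=bool)
    for tree in model.trees_:
        base += model.eta * _tree_expectation(tree, X[0], none)
        for i in range(n):
            phi[i] += model.eta * _shap_one_tree(tree, X[i], p)
    return ShapMatrix(values=phi, base_value=float(base), feature_names=model.feature_names_)


def shap_importance(shap: ShapMatrix) -> pd.DataFrame:
    """Predictor-wise mean absolute SHAP value, ranked descending
    (ties by predictor index)."""
    if shap.values.size == 0:
        raise ValueError("empty SHAP matrix")
    imp = np.abs(shap.values).mean(axis=0)
    names = shap.feature_names or [f"x{j}" for j in range(len(imp))]
    order = np.lexsort((np.arange(len(imp)), -imp))
    return pd.DataFrame(
        {"predictor": [names[j] for j in order], "importance": imp[order]}
    ).reset_index(drop=True)


@dataclass
class AleProfile:
    """Centered accumulated-local-effects profile of one predictor."""

    predictor: int
    edges: np.ndarray       # bin edges, length n_bins + 1
    effects: np.ndarray     # centered ALE value at each upper edge
    counts: np.ndarray      # samples per bin

    @property
    def importance(self) -> float:
        return float(self.effects.max() - self.effects.min())


def ale_profile(predict, X, predictor: int, n_bins: int = 40) -> AleProfile:
    """ALE main effect of one predictor over quantile bins.

    ``predict`` is any callable mapping an (n, p) array to predictions.
    Local effects average, over in-bin samples, the prediction change
    when the predictor moves from the bin's lower to upper edge with the
    other predictors at their observed values; effects are accumulated
    and centered to zero bin-count-weighted mean.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    X = np.asarray(X, dtype=float)
    col = X[:, predictor]
    distinct = np.unique(col)
    if distinct.size < 2:
        raise ValueError("predictor has fewer than 2 distinct values")
    n_bins = min(n_bins, distinct.size - 1)
    edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)))
    n_bins = len(edges) - 1
    bin_idx = np.clip(np.searchsorted(edges, col, side="left") - 1, 0, n_bins - 1)
    local = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        rows = np.flatnonzero(bin_idx == b)
        counts[b] = rows.size
        if rows.size == 0:
            continue
        lo = X[rows].copy()
        hi = X[rows].copy()
        lo[:, predictor] = edges[b]
        hi[:, predictor] = edges[b + 1]
        local[b] = float(np.mean(predict(hi) - predict(lo)))
    acc = np.cumsum(local)
    center = float(np.sum(acc * counts) / counts.sum())
    return AleProfile(predictor=predictor, edges=edges, effects=acc - center, counts=counts)


def ale_profiles(model, X, n_bins: int = 40) -> list[AleProfile]:
    """ALE profiles of all predictors of a fitted model."""
    X = np.asarray(X, dtype=float)
    return [
        ale_profile(model.predict, X, j, n_bins=n_bins) for j in range(X.shape[1])
    ]


def ale_importance(
    profiles: list[AleProfile],
    highlight_threshold: float = 1.5,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Rank predictors by ALE range (max - min of the centered profile);
    ``highlighted`` marks profiles with range above the threshold."""
    imp = np.array([p.importance for p in profiles])
    idx = np.array([p.predictor for p in profiles])
    order = np.lexsort((idx, -imp))
    names = feature_names or [f"x{j}" for j in idx]
    return pd.DataFrame(
        {
            "predictor": [names[o] for o in order],
            "importance": imp[order],
            "highlighted": imp[order] > highlight_threshold,
        }
    ).reset_index(drop=True)


class SurrogateTree(BaseEstimator):
    """Shallow inference tree distilling a model's predictions.

    At each node the predictor with the smallest permutation p-value of
    |Pearson r| with the model predictions is selected; the split is
    placed at the SSE-optimal threshold.  A node stays a leaf when the
    multiplicity-adjusted p-value ``1 - (1-p_min)^n_predictors`` exceeds
    ``alpha``, when it holds fewer than ``2 * min_node`` samples, or
    when ``max_inner_nodes`` is reached (breadth-first growth).
    """

    def __init__(
        self,
        max_inner_nodes: int = 5,
        alpha: float = 0.05,
        min_node: int = 5,
        n_perm: int = 999,
        random_state: int = 0,
    ):
        self.max_inner_nodes = max_inner_nodes
        self.alpha = alpha
        self.min_node = min_node
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y_model):
        """``y_model`` are the full model's predictions on ``X``."""
        X_df = X if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y_model, dtype=float)
        if len(y) < 20:
            raise ValueError("surrogate fitting requires at least 20 samples")
        rng = np.random.default_rng(self.random_state)
        tree = RegressionTree()
        sstot = float(np.sum((y - y.mean()) ** 2))
        if sstot == 0:
            warnings.warn("constant model predictions: single-leaf surrogate, fidelity undefined")
            tree._new_node(float(y.mean()), len(y))
            self.tree_ = tree
            self.fidelity_r2_ = np.nan
            self.feature_names_ = list(X_df.columns) if X_df is not None else None
            return self

        inner = 0
        queue = []
        root = tree._new_node(float(y.mean()), len(y))
        queue.append((root, np.arange(len(y))))
        while queue and inner < self.max_inner_nodes:
            node, rows = queue.pop(0)
            if rows.size < 2 * self.min_node:
                continue
            f, p_adj = self._select_predictor(X[rows], y[rows], rng)
            if f is None or p_adj > self.alpha:
                continue
            found = _best_split(X[rows][:, [f]], y[rows], self.min_node)
            if found is None:
                continue
            _, thr, _ = found
            tree.feature[node] = int(f)
            tree.threshold[node] = float(thr)
            go_left = X[rows, f] < thr
            left = tree._new_node(float(y[rows[go_left]].mean()), int(go_left.sum()))
            right = tree._new_node(float(y[rows[~go_left]].mean()), int((~go_left).sum()))
            tree.left[node], tree.right[node] = left, right
            inner += 1
            queue.append((left, rows[go_left]))
            queue.append((right, rows[~go_left]))

        self.tree_ = tree
        fitted = tree.predict(X)
        self.fidelity_r2_ = float(1.0 - np.sum((y - fitted) ** 2) / sstot)
        self.feature_names_ = list(X_df.columns) if X_df is not None else None
        return self

    def _select_predictor(self, X, y, rng):
        """Smallest permutation p of |Pearson r|, Bonferroni-style adjusted."""
        yc = y - y.mean()
        sy = np.sqrt(np.sum(yc**2))
        Xc = X - X.mean(axis=0)
        sx = np.sqrt(np.sum(Xc**2, axis=0))
        usable = sx > 0
        if sy == 0 or not usable.any():
            return None, 1.0
        r_obs = np.zeros(X.shape[1])
        r_obs[usable] = np.abs(Xc[:, usable].T @ yc) / (sx[usable] * sy)
        perms = np.stack([rng.permutation(yc) for _ in range(self.n_perm)], axis=1)
        r_perm = np.abs(Xc[:, usable].T @ perms) / (sx[usable, None] * sy)
        exceed = (r_perm >= r_obs[usable, None] - 1e-12).sum(axis=1)
        p = (1 + exceed) / (1 + self.n_perm)
        best_local = int(np.argmin(p))
        best = int(np.flatnonzero(usable)[best_local])
        m = int(usable.sum())
        p_adj = min(1.0, 1.0 - (1.0 - float(p[best_local])) ** m)
        return best, p_adj

    def predict(self, X) -> np.ndarray:
        self._check_fitted("tree_")
        return self.tree_.predict(np.asarray(X, dtype=float))

    @property
    def n_inner_nodes_(self) -> int:
        self._check_fitted("tree_")
        return sum(f >= 0 for f in self.tree_.feature)

    def to_dict(self) -> dict:
        self._check_fitted("tree_")
        return {
            "params": self.get_params(),
            "tree": self.tree_.to_dict(),
            "fidelity_r2": None if np.isnan(self.fidelity_r2_) else self.fidelity_r2_,
            "feature_names": self.feature_names_,
        }
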