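"""Non-negative generalized low-rank archetype decomposition.

The core ASV relative-abundance table A (samples x ASVs) is column
centered and factorized as ``A_c ~ X @ Y`` with unconstrained sample
scores X and elementwise non-negative loadings Y.  Each row of Y is an
"archetype": a latent community profile; the matching column of X
quantifies its presence in each sample.

Fitting is greedy sequential deflation: each component is an
alternating rank-1 minimization against the current residual
(unconstrained least-squares score step, non-negative least-squares
loading step, both closed-form), after which the residual is deflated.
The quadratic objective is non-increasing within and across components,
ranks are nested by construction, and — because the score step leaves
the residual orthogonal to its component — the per-component variance
shares ``||x_j y_j||_F^2 / ||A_c||_F^2`` are exact, non-negative and
sum to at most 1.  On data with orthogonal factors the decomposition
coincides with PCA.  Components explaining more than ``1/n_asvs`` of
the variance are selected.  Selected score columns are
turned into model predictors by a Manly exponential transform
``(exp(lam*x)-1)/lam`` (lambda per column by profile likelihood over a
grid, identity at lambda=0) followed by centering and unit scaling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._base import BaseEstimator

__all__ = ["ArchetypeGLRM", "manly_transform", "fit_manly_lambda", "engineer_predictors"]


def manly_transform(x: np.ndarray, lam: float) -> np.ndarray:
    """Manly exponential transform ``(exp(lam*x) - 1)/lam``; identity at 0."""
    x = np.asarray(x, dtype=float)
    if abs(lam) < 1e-12:
        return x.copy()
    return np.expm1(lam * x) / lam


def fit_manly_lambda(x: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Choose lambda by profile (normal) likelihood over a grid in [-2, 2].

    The log-likelihood is ``-n/2 log(var(y)) + lam * sum(x)`` where the
    second term is the log-Jacobian of the transform.
    """
    x = np.asarray(x, dtype=float)
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 81)
    n = x.size
    best_lam, best_ll = 0.0, -np.inf
    sx = float(x.sum())
    for lam in grid:
        y = manly_transform(x, lam)
        var = float(np.var(y))
        if not np.isfinite(var) or var <= 0:
            continue
        ll = -0.5 * n * np.log(var) + lam * sx
        if ll > best_ll + 1e-12:
            best_ll, best_lam = ll, float(lam)
    return best_lam


class ArchetypeGLRM(BaseEstimator):
    """Quadratic-loss GLRM with non-negative loadings, fitted by greedy
    rank-1 deflation with alternating closed-form steps.

    Parameters
    ----------
    n_components:
        Rank k; ``"auto"`` uses ``min(n_samples - 1, 40)``.
    max_iter, tol:
        Each rank-1 alternation stops at relative objective improvement
        below ``tol`` or after ``max_iter`` sweeps.
    n_init:
        Extra random starts per component beyond the deterministic
        SVD-based pair; the best rank-1 objective wins.
    random_state:
        Seed of the random starts.

    Attributes
    ----------
    column_means_ : per-ASV mean relative abundance.
    X_ : (n_samples, k) training scores.
    components_ : (k, n_asvs) non-negative loadings, share-ordered.
    variance_shares_ : per-component share of ||A_c||_F^2.
    selected_ : indices of components with share > 1/n_asvs.
    objective_history_ : residual sum of squares after each deflation
        step (first entry: before any component).
    """

    def __init__(
        self,
        n_components: int | str = "auto",
        max_iter: int = 200,
        tol: float = 1e-7,
        n_init: int = 1,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------
    def fit(self, A: pd.DataFrame | np.ndarray):
        A_df = A if isinstance(A, pd.DataFrame) else None
        A = np.asarray(A, dtype=float)
        if not np.all(np.isfinite(A)):
            raise ValueError("input matrix contains non-finite values")
        n, p = A.shape
        k = min(n - 1, 40) if self.n_components == "auto" else int(self.n_components)
        if k <= 0:
            raise ValueError("n_components must be positive")
        if k > min(n, p):
            raise ValueError(f"n_components={k} exceeds min(n_samples, n_asvs)")

        mu = A.mean(axis=0)
        Ac = A - mu
        total = float(np.sum(Ac**2))

        rng = np.random.default_rng(self.random_state)
        X, Y, history = self._fit_sequential(Ac, k, rng)
        # rank-1 residuals are orthogonal to their component, so the
        # telescoping identity gives exact non-negative shares
        shares = (np.linalg.norm(X, axis=0) * np.linalg.norm(Y, axis=1)) ** 2
        shares = shares / max(total, 1e-30)
        order = np.argsort(-shares, kind="stable")
        X, Y, shares = X[:, order], Y[order], shares[order]
        self.column_means_ = mu
        self.X_ = X
        self.components_ = Y
        self.variance_shares_ = shares
        self.selected_ = np.flatnonzero(shares > 1.0 / p)
        if self.selected_.size == 0:
            warnings.warn("no component exceeds the 1/n_asvs variance-share threshold")
        self.objective_history_ = np.asarray(history)
        self.n_iter_ = len(history) - 1
        self.feature_names_ = list(A_df.columns) if A_df is not None else None
        self.sample_names_ = list(A_df.index) if A_df is not None else None
        return self

    def _rank_one(self, R, x0):
        """Alternating rank-1 fit to residual R: unconstrained score step,
        non-negative loading step (both closed-form)."""
        x = x0.copy()
        prev = None
        for _ in range(self.max_iter):
            xx = float(x @ x)
            if xx == 0:
                return np.zeros_like(x), np.zeros(R.shape[1]), np.inf
            y = np.clip(R.T @ x / xx, 0.0, None)
            yy = float(y @ y)
            if yy == 0:
                return np.zeros_like(x), y, float(np.sum(R**2))
            x = R @ y / yy
            obj = float(np.sum((R - np.outer(x, y)) ** 2))
            if prev is not None and prev - obj <= self.tol * max(prev, 1e-30):
                break
            prev = obj
        return x, y, obj

    def _fit_sequential(self, Ac, k, rng):
        """Greedy deflation: each archetype is the best rank-1 term of the
        current residual; the total objective is non-increasing both within
        and across components, and ranks are nested by construction."""
        n, p = Ac.shape
        X = np.zeros((n, k))
        Y = np.zeros((k, p))
        R = Ac.copy()
        history = [float(np.sum(R**2))]
        for j in range(k):
            U, s, _ = np.linalg.svd(R, full_matrices=False)
            starts = [U[:, 0] * s[0], -U[:, 0] * s[0]]
            starts += [rng.normal(size=n) for _ in range(max(0, self.n_init - 1))]
            best = None
            for x0 in starts:
                x, y, obj = self._rank_one(R, x0)
                if best is None or obj < best[2] - 1e-15:
                    best = (x, y, obj)
            x, y, obj = best
            X[:, j] = x
            Y[j] = y
            R = R - np.outer(x, y)
            history.append(float(np.sum(R**2)))
        return X, Y, history

    # -- downstream ------------------------------------------------------
    def transform(self, A: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Scores of new samples: least squares against the fitted loadings."""
        self._check_fitted("components_")
        A = np.asarray(A, dtype=float)
        Ac = A - self.column_means_
        return np.linalg.lstsq(self.components_.T, Ac.T, rcond=None)[0].T

    def fit_transform(self, A) -> np.ndarray:
        return self.fit(A).X_

    def reconstruct(self, subset=None, X: np.ndarray | None = None) -> pd.DataFrame:
        """Reconstructed relative abundances from a component subset.

        ``mu + X[:, S] @ Y[S, :]`` with negatives clipped to 0 and rows
        renormalized to sum 1.  An empty subset returns the mean
        composition for every sample (with a warning).
        """
        self._check_fitted("components_")
        X = self.X_ if X is None else np.asarray(X, dtype=float)
        k = self.components_.shape[0]
        S = np.arange(k) if subset is None else np.asarray(list(subset), dtype=int)
        if S.size and (S.min() < 0 or S.max() >= k):
            raise ValueError("subset indices outside the fitted components")
        if S.size == 0:
            warnings.warn("empty component subset: returning the mean composition")
            rec = np.tile(self.column_means_, (X.shape[0], 1))
        else:
            rec = self.column_means_ + X[:, S] @ self.components_[S]
        rec = np.clip(rec, 0.0, None)
        sums = rec.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        rec = rec / sums
        cols = self.feature_names_ if self.feature_names_ is not None else None
        idx = self.sample_names_ if self.sample_names_ is not None else None
        return pd.DataFrame(rec, columns=cols, index=idx)


def engineer_predictors(
    model: ArchetypeGLRM,
    alpha: pd.DataFrame | None = None,
    lambda_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Build the centered/scaled predictor table for REI prediction.

    Each selected score column is Manly-transformed (lambda fitted per
    column), centered and scaled to unit sd; the Gini-Simpson and
    Simpson-evenness columns of ``alpha`` are appended and likewise
    standardized.  Returns (predictor table, lambda per component).
    Zero-variance columns are dropped with a warning.
    """
    model._check_fitted("components_")
    if model.selected_.size == 0:
        raise ValueError("no selected components to engineer predictors from")
    index = model.sample_names_ if model.sample_names_ is not None else range(model.X_.shape[0])
    cols: dict[str, np.ndarray] = {}
    lambdas: dict[str, float] = {}
    for j in model.selected_:
        name = f"Arch{j + 1}"
        x = model.X_[:, j]
        lam = fit_manly_lambda(x, lambda_grid)
        cols[name] = manly_transform(x, lam)
        lambdas[name] = lam
    if alpha is not None:
        for name in ("gini_simpson", "simpson_evenness"):
            if name not in alpha.columns:
                raise ValueError(f"alpha table missing column {name!r}")
            cols[name] = alpha[name].to_numpy(dtype=float)
    out = {}
    for name, x in cols.items():
        sd = x.std()
        if sd == 0:
            warnings.warn(f"predictor {name} has zero variance and was dropped")
            lambdas.pop(name, None)
            continue
        out[name] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=index), lambdas
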