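"""REI-associated co-occurrence network from reconstructed abundances.

A sparse Gaussian graphical model is estimated on the column-scaled
reconstructed ASV table by the graphical lasso (block coordinate
descent with an L1 penalty on off-diagonal precision entries), with the
penalty chosen on a 100-point log grid by the extended Bayesian
information criterion

    EBIC(lambda) = -2 loglik(Omega) + |E| log n + 4 |E| gamma log p

(gamma = 0.5 by default).  Edges are the non-zero partial correlations
``rho_ij = -omega_ij / sqrt(omega_ii omega_jj)``.  Hub scores are the
principal eigenvector of the |rho|-weighted adjacency scaled to max 1;
modules come from cutting the UPGMA tree of the partial-correlation
distance (1 - rho) at a quantile of the merge-height range controlled
by ``deep_split``, keeping branches with at least ``min_size`` leaves.
"""

from __future__ import annotations

import warnings

import numba
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._base import BaseEstimator
from .community import rank_group_tests

__all__ = [
    "glasso",
    "GraphicalLassoEBIC",
    "network_sparsity",
    "hub_scores",
    "asv_rei_coefficients",
    "detect_modules",
    "pearson_test",
    "module_rei_stats",
    "hub_rei_correlation",
    "module_component_association",
]


@numba.njit(cache=True)
def _glasso_core(S, lam, W, B, max_iter, tol, inner_max, inner_tol):  # pragma: no cover
    p = S.shape[0]
    off_scale = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                off_scale += abs(S[i, j])
    off_scale = max(off_scale / max(p * (p - 1), 1), 1e-12)
    grad = np.zeros(p)
    for _ in range(max_iter):
        w_delta = 0.0
        for j in range(p):
            # coordinate descent for column j's lasso subproblem with an
            # incrementally maintained gradient g[k] = sum_{l!=j} W[k,l] B[l,j]
            for k in range(p):
                g = 0.0
                for l in range(p):
                    if l != j:
                        g += W[k, l] * B[l, j]
                grad[k] = g
            for _inner in range(inner_max):
                delta_max = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    old = B[k, j]
                    z = S[k, j] - grad[k] + W[k, k] * old
                    if z > lam:
                        new = (z - lam) / W[k, k]
                    elif z < -lam:
                        new = (z + lam) / W[k, k]
                    else:
                        new = 0.0
                    if new != old:
                        delta = new - old
                        B[k, j] = new
                        for l in range(p):
                            grad[l] += W[l, k] * delta
                        if abs(delta) > delta_max:
                            delta_max = abs(delta)
                if delta_max < inner_tol:
                    break
            for k in range(p):
                if k == j:
                    continue
                w = grad[k]
                if abs(w - W[k, j]) > w_delta:
                    w_delta = abs(w - W[k, j])
                W[k, j] = w
                W[j, k] = w
        if w_delta < tol * off_scale:
            break


def glasso(
    S: np.ndarray,
    lam: float,
    max_iter: int = 50,
    tol: float = 1e-4,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Graphical lasso by block coordinate descent (Friedman et al. scheme).

    Minimizes ``-logdet(Omega) + tr(S Omega) + lam * sum_{i!=j} |omega_ij|``
    (off-diagonal penalty only).  Returns (Omega, W=Sigma estimate,
    warm-start state).
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    if warm is None:
        W = S.copy()
        B = np.zeros((p, p))
    else:
        W, B = warm[0].copy(), warm[1].copy()
        np.fill_diagonal(W, np.diag(S))
    _glasso_core(S, float(lam), W, B, max_iter, tol, 100, 1e-6)
    Omega = np.zeros((p, p))
    for j in range(p):
        nj = np.array([i for i in range(p) if i != j])
        denom = W[j, j] - W[nj, j] @ B[nj, j]
        Omega[j, j] = 1.0 / denom
        Omega[nj, j] = -B[nj, j] * Omega[j, j]
    Omega = 0.5 * (Omega + Omega.T)
    return Omega, W, (W, B)


def _partial_corr(Omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(Omega))
    rho = -Omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


class GraphicalLassoEBIC(BaseEstimator):
    """Sparse Gaussian graphical model tuned by EBIC over a lambda grid.

    Attributes (after fit): ``precision_``, ``partial_corr_``,
    ``lambda_``, ``edges_`` (list of (i, j, rho)), ``sparsity_``,
    ``ebic_grid_`` (DataFrame lambda/n_edges/ebic).
    """

    def __init__(
        self,
        lambda_grid: np.ndarray | None = None,
        n_lambda: int = 100,
        gamma: float = 0.5,
        max_iter: int = 50,
        tol: float = 1e-4,
        edge_tol: float = 1e-8,
    ):
        self.lambda_grid = lambda_grid
        self.n_lambda = n_lambda
        self.gamma = gamma
        self.max_iter = max_iter
        self.tol = tol
        self.edge_tol = edge_tol

    def fit(self, Z: pd.DataFrame | np.ndarray):
        Z_df = Z if isinstance(Z, pd.DataFrame) else None
        Z = np.asarray(Z, dtype=float)
        n, p = Z.shape
        if n < 3:
            raise ValueError("need at least 3 samples")
        sd = Z.std(axis=0)
        if (sd == 0).any():
            raise ValueError("zero-variance columns cannot enter the network")
        Zs = (Z - Z.mean(axis=0)) / sd
        S = Zs.T @ Zs / n
        eig_min = np.linalg.eigvalsh(S).min()
        if eig_min < 1e-8:
            # rank-deficient inputs (e.g. low-rank reconstructions) get a
            # small ridge toward the identity so the penalized likelihood
            # stays well conditioned along the whole lambda path
            warnings.warn("empirical correlation not positive definite: ridge jitter applied")
            S = (1.0 - 1e-3) * S + 1e-3 * np.eye(p)

        if self.lambda_grid is None:
            lam_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
            grid = np.geomspace(0.01 * lam_max, lam_max, self.n_lambda)
        else:
            grid = np.sort(np.asarray(self.lambda_grid, dtype=float))

        rows = []
        best = None
        warm = None
        for lam in grid[::-1]:  # large to small, warm-started
            Omega, W, warm = glasso(S, lam, self.max_iter, self.tol, warm=warm)
            rho = _partial_corr(Omega)
            mask = np.triu(np.abs(rho) > self.edge_tol, 1)
            n_edges = int(mask.sum())
            sign, logdet = np.linalg.slogdet(Omega)
            if sign <= 0:
                ebic = np.inf
            else:
                loglik = 0.5 * n * (logdet - np.trace(S @ Omega))
                ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * self.gamma * np.log(p)
            rows.append({"lambda": float(lam), "n_edges": n_edges, "ebic": float(ebic)})
            if best is None or ebic < best[0] - 1e-12:
                best = (ebic, lam, Omega, rho)

        _, lam, Omega, rho = best
        self.precision_ = Omega
        self.partial_corr_ = rho
        self.lambda_ = float(lam)
        names = list(Z_df.columns) if Z_df is not None else list(range(p))
        self.feature_names_ = names
        self.edges_ = [
            (names[i], names[j], float(rho[i, j]))
            for i, j in zip(*np.where(np.triu(np.abs(rho) > self.edge_tol, 1)))
        ]
        self.sparsity_ = len(self.edges_) / (p * (p - 1) / 2)
        self.ebic_grid_ = pd.DataFrame(rows).sort_values("lambda").reset_index(drop=True)
        return self


def network_sparsity(fit: GraphicalLassoEBIC) -> float:
    """Fraction of possible edges present in the selected network."""
    fit._check_fitted("edges_")
    return float(fit.sparsity_)


def hub_scores(partial_corr: np.ndarray, edge_tol: float = 1e-8) -> np.ndarray:
    """Principal-eigenvector centrality of the |rho|-weighted graph, max 1.

    For an undirected graph the Kleinberg hub and authority scores
    coincide with eigenvector centrality.
    """
    A = np.abs(np.asarray(partial_corr, dtype=float))
    np.fill_diagonal(A, 0.0)
    A[A <= edge_tol] = 0.0
    if not A.any():
        warnings.warn("empty edge set: all hub scores 0")
        return np.zeros(A.shape[0])
    vals, vecs = np.linalg.eigh(A)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()


def asv_rei_coefficients(abundances: pd.DataFrame, rei: pd.Series) -> pd.Series:
    """Per-ASV REI association: slope of centered REI on centered
    abundance with the intercept fixed at the REI mean (``cov/var``)."""
    rei = rei.loc[abundances.index]
    y = rei.to_numpy(dtype=float)
    yc = y - y.mean()
    out = {}
    for col in abundances.columns:
        x = abundances[col].to_numpy(dtype=float)
        var = np.var(x)
        if var == 0:
            warnings.warn(f"zero-variance ASV {col}: coefficient undefined")
            out[col] = np.nan
        else:
            out[col] = float(np.mean((x - x.mean()) * yc) / var)
    return pd.Series(out, name="rei_coefficient")


#: deep_split -> quantile of the merge-height distribution at which the
#: tree is cut; higher deep_split cuts lower, giving more, finer modules
_DEEP_SPLIT_Q = {0: 0.98, 1: 0.95, 2: 0.92, 3: 0.88, 4: 0.84}


def detect_modules(
    partial_corr: np.ndarray,
    min_size: int = 10,
    deep_split: int = 2,
    labels: list | None = None,
) -> pd.Series:
    """Dendrogram modules of the partial-correlation distance (1 - rho).

    The UPGMA tree is cut at a quantile of its merge-height distribution
    (coarse at deep_split 0, fine at 4); branches with at least
    ``min_size`` leaves become modules numbered by decreasing size,
    everything else is labelled 0 (unassigned).  Deterministic.
    """
    if deep_split not in _DEEP_SPLIT_Q:
        raise ValueError("deep_split must be one of 0..4")
    rho = np.asarray(partial_corr, dtype=float)
    p = rho.shape[0]
    if min_size > p / 2:
        warnings.warn("min_size exceeds half the nodes: at most one module possible")
    if p < 2 * min_size:
        warnings.warn("fewer than 2*min_size nodes")
    D = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, _DEEP_SPLIT_Q[deep_split]))
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size].index
    # renumber modules by decreasing size, ties by first appearance
    mapping = {old: new + 1 for new, old in enumerate(keep)}
    out = np.array([mapping.get(r, 0) for r in raw], dtype=int)
    if labels is None:
        labels = list(range(p))
    return pd.Series(out, index=labels, name="module")


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided Student-t p-value
    ``t = r sqrt(n-2)/sqrt(1-r^2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p


def module_rei_stats(
    scaled_abundances: pd.DataFrame,
    modules: pd.Series,
    rei: pd.Series,
    summary: str = "mean",
) -> pd.DataFrame:
    """Per-module REI correlation.

    The module summary per sample is the mean of member ASVs' scaled
    abundances (or the first principal component with
    ``summary='eigen'``); association is Pearson r with Student-t p.
    """
    if summary not in ("mean", "eigen"):
        raise ValueError("summary must be 'mean' or 'eigen'")
    rei = rei.loc[scaled_abundances.index].to_numpy(dtype=float)
    rows = []
    for mod in sorted(m for m in modules.unique() if m != 0):
        members = modules.index[modules == mod]
        sub = scaled_abundances[members].to_numpy(dtype=float)
        if summary == "mean":
            score = sub.mean(axis=1)
        else:
            sub_c = sub - sub.mean(axis=0)
            _, _, Vt = np.linalg.svd(sub_c, full_matrices=False)
            score = sub_c @ Vt[0]
            if np.corrcoef(score, sub.mean(axis=1))[0, 1] < 0:
                score = -score
        r, p = pearson_test(score, rei)
        rows.append({"module": mod, "n_asvs": len(members), "pearson_r": r, "p": p})
    return pd.DataFrame(rows)


def hub_rei_correlation(hub: np.ndarray, beta: np.ndarray) -> tuple[float, float]:
    """Correlation between node hub scores and per-ASV REI coefficients."""
    hub = np.asarray(hub, dtype=float)
    beta = np.asarray(beta, dtype=float)
    ok = np.isfinite(beta)
    return pearson_test(hub[ok], beta[ok])


def module_component_association(
    modules: pd.Series, loadings: pd.DataFrame
) -> pd.DataFrame:
    """Kruskal-Wallis of per-ASV component loadings across modules.

    ``loadings`` is components x ASVs (rows named per component).
    Unassigned ASVs (module 0) are excluded; at least 2 modules required.
    """
    assigned = modules[modules != 0]
    if assigned.nunique() < 2:
        raise ValueError("need at least 2 modules")
    rows = []
    for comp in loadings.index:
        vals = loadings.loc[comp, assigned.index]
        res = rank_group_tests(vals.to_numpy(), assigned.to_numpy())
        rows.append({"component": comp, "H": res["H"], "p": res["p"]})
    return pd.DataFrame(rows)
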