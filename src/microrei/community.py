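"""Community profiling: core-ASV filtering, diversity, dissimilarity,
permutation tests, and phylogeny utilities.

Counts tables are pandas DataFrames with samples as rows and ASVs as
columns; all joins are by label, never by position.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "AsvTable",
    "relative_abundance",
    "filter_core_asvs",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "bray_curtis_matrix",
    "divergence",
    "permanova",
    "rank_group_tests",
    "jukes_cantor",
    "UpgmaTree",
    "upgma",
    "phylogeny_cluster_association",
]


@dataclass
class AsvTable:
    """Counts with relative abundances, optional taxonomy and core mask."""

    counts: pd.DataFrame                 # samples x ASVs
    relative: pd.DataFrame               # rows sum to 1
    taxonomy: pd.DataFrame | None = None  # per-ASV ranks
    core_mask: pd.Series | None = None    # boolean per original ASV


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to per-sample relative abundances."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    return counts.div(totals, axis=0)


def filter_core_asvs(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    min_rel: float = 0.001,
    min_prev: float = 0.5,
) -> AsvTable:
    """Keep ASVs whose relative abundance exceeds ``min_rel`` (strictly)
    in at least ``ceil(min_prev * n_samples)`` samples.

    Relative abundances are recomputed on the kept set.
    """
    if counts.empty:
        raise ValueError("empty ASV table")
    rel = relative_abundance(counts)
    n = len(counts)
    need = math.ceil(min_prev * n)
    prevalent = (rel > min_rel).sum(axis=0) >= need
    if not prevalent.any():
        raise ValueError(
            f"no ASV exceeds {min_rel:.4g} relative abundance in >= {need} samples; "
            "lower min_rel or min_prev"
        )
    kept = counts.loc[:, prevalent]
    tax = taxonomy.loc[taxonomy.index.intersection(kept.columns)] if taxonomy is not None else None
    return AsvTable(
        counts=kept,
        relative=relative_abundance(kept),
        taxonomy=tax,
        core_mask=prevalent,
    )


def alpha_diversity(p: np.ndarray) -> tuple[float, float]:
    """Gini-Simpson diversity and Simpson evenness of one composition.

    ``gini_simpson = 1 - sum(p^2)``; ``simpson_evenness =
    (1/sum(p^2)) / S`` with S the number of non-zero taxa.
    """
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"abundance vector must sum to 1, sums to {total:.6g}")
    ssq = float(np.sum(p**2))
    s = int(np.count_nonzero(p))
    return 1.0 - ssq, (1.0 / ssq) / s


def alpha_diversity_table(rel: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Gini-Simpson and Simpson evenness from a relative table."""
    rows = [alpha_diversity(rel.loc[s].to_numpy()) for s in rel.index]
    return pd.DataFrame(rows, index=rel.index, columns=["gini_simpson", "simpson_evenness"])


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray-Curtis dissimilarity of a samples x features table."""
    X = table.to_numpy(dtype=float)
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        D = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=table.index, columns=table.index)


def divergence(
    table: pd.DataFrame, groups: pd.Series, reference: str = "mean"
) -> pd.Series:
    """Per-sample beta diversity: Bray-Curtis distance to the sample's
    group reference composition (group mean by default, ``median`` by flag).
    """
    if reference not in ("mean", "median"):
        raise ValueError("reference must be 'mean' or 'median'")
    groups = groups.loc[table.index]
    out = pd.Series(index=table.index, dtype=float, name="divergence")
    for g, idx in table.groupby(groups).groups.items():
        sub = table.loc[idx]
        ref = sub.mean(axis=0) if reference == "mean" else sub.median(axis=0)
        for s in idx:
            out.loc[s] = bray_curtis(table.loc[s].to_numpy(), ref.to_numpy())
    return out


def _permanova_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    g = len(uniq)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    D: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool | None = None,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    ``F = (SS_between/(g-1)) / (SS_within/(n-g))`` with sums of squared
    distances; the p-value permutes group labels.  When the number of
    distinct label arrangements is at most ``n_perm`` (or ``exhaustive``
    is forced) all arrangements are enumerated and the p-value is the
    exact fraction with ``F >= F_obs``; otherwise Monte-Carlo sampling
    with the +1 correction is used, so the minimum attainable p is
    ``1/(n_perm+1)``.
    """
    if isinstance(D, pd.DataFrame):
        labels = pd.Series(labels).to_numpy() if not isinstance(labels, pd.Series) else labels.loc[D.index].to_numpy()
        D = D.to_numpy(dtype=float)
    else:
        D = np.asarray(D, dtype=float)
        labels = np.asarray(labels)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("permanova requires at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 are not allowed: {small}")

    d2 = D**2
    f_obs = _permanova_f(d2, labels, uniq)

    n = len(labels)
    n_arrangements = math.factorial(n)
    for c in counts:
        n_arrangements //= math.factorial(int(c))
    if exhaustive is None:
        exhaustive = n_arrangements <= n_perm

    if exhaustive:
        count = 0
        total = 0
        for perm in _multiset_permutations(labels):
            f = _permanova_f(d2, perm, uniq)
            count += f >= f_obs - 1e-12
            total += 1
        return f_obs, count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f = _permanova_f(d2, rng.permutation(labels), uniq)
        count += f >= f_obs - 1e-12
    return f_obs, (1 + count) / (1 + n_perm)


def _multiset_permutations(labels: np.ndarray):
    """All distinct arrangements of a label multiset."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)

    def rec(positions, remaining):
        if not remaining:
            yield []
            return
        g, c = remaining[0]
        for combo in itertools.combinations(positions, c):
            rest = [p for p in positions if p not in set(combo)]
            for tail in rec(rest, remaining[1:]):
                yield list(combo) + tail

    remaining = list(zip(uniq, counts))
    for placement in rec(list(range(n)), remaining):
        out = np.empty(n, dtype=labels.dtype)
        pos = 0
        for g, c in remaining:
            for p in placement[pos : pos + int(c)]:
                out[p] = g
            pos += int(c)
        yield out


def rank_group_tests(values, groups) -> dict:
    """Kruskal-Wallis across groups plus pairwise two-sided rank-sum tests.

    The Kruskal-Wallis H is tie-corrected with a chi-square p; pairwise
    Mann-Whitney tests use the exact distribution for small tie-free
    groups and the tie-corrected normal approximation otherwise.
    """
    values = pd.Series(values).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    by_group = {g: values[groups == g].to_numpy(dtype=float) for g in groups.unique()}
    if len(by_group) < 2:
        raise ValueError("rank_group_tests requires at least 2 groups")
    for g, v in by_group.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    samples = list(by_group.values())
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    pairwise = {}
    for (ga, xa), (gb, xb) in itertools.combinations(by_group.items(), 2):
        if np.ptp(np.concatenate([xa, xb])) == 0:
            pairwise[(ga, gb)] = 1.0
        else:
            pairwise[(ga, gb)] = float(
                stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto").pvalue
            )
    return {"H": float(h), "p": float(p), "pairwise": pairwise}


_VALID_BASES = frozenset("ACGT")


def jukes_cantor(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance ``-(3/4) ln(1 - 4p/3)`` between aligned sequences.

    The mismatch proportion p is computed over columns where both
    sequences carry an unambiguous A/C/G/T (gaps and ambiguity codes are
    ignored).  ``p >= 0.75`` has no defined distance and raises.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    valid = mismatch = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _VALID_BASES and b in _VALID_BASES:
            valid += 1
            mismatch += a != b
    if valid == 0:
        raise ValueError("no ungapped comparable columns")
    p = mismatch / valid
    if p >= 0.75:
        raise ValueError(f"mismatch proportion {p:.3f} >= 0.75: JC distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class UpgmaTree:
    """Rooted ultrametric tree from size-weighted average-linkage clustering."""

    linkage: np.ndarray      # scipy linkage matrix
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        """Heights of internal nodes (half the merge distance)."""
        return self.linkage[:, 2] / 2.0

    def cophenetic(self) -> pd.DataFrame:
        """Leaf-to-leaf cophenetic distances implied by the tree."""
        d = hierarchy.cophenet(self.linkage)
        return pd.DataFrame(squareform(d), index=self.labels, columns=self.labels)

    def newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            height = node.dist / 2.0
            length = parent_height - height
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, height)
            right = rec(node.right, height)
            return f"({left},{right}):{length:.6g}"

        height = root.dist / 2.0
        left = rec(root.left, height)
        right = rec(root.right, height)
        return f"({left},{right});"


def upgma(D: pd.DataFrame | np.ndarray, labels=None) -> UpgmaTree:
    """UPGMA clustering of a distance matrix (size-weighted averaging)."""
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        D = D.to_numpy(dtype=float)
    else:
        D = np.asarray(D, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(D.shape[0])]
    if not np.allclose(D, D.T) or (np.diag(D) != 0).any():
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return UpgmaTree(linkage=Z, labels=list(labels))


def phylogeny_cluster_association(
    D_phylo: pd.DataFrame, cluster_labels: pd.Series, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Test whether phylogenetic distances are independent of cluster labels
    (permutational multivariate ANOVA on the phylogenetic distance matrix).
    """
    labels = pd.Series(cluster_labels)
    missing = [l for l in D_phylo.index if l not in labels.index]
    if missing:
        raise ValueError(f"cluster labels missing for leaves: {missing[:5]}")
    labels = labels.loc[D_phylo.index]
    if labels.nunique() < 2:
        raise ValueError("at least 2 clusters are required")
    return permanova(D_phylo, labels, n_perm=n_perm, seed=seed)
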