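"""Ordered-three-group metagenome statistics.

Pipeline for gene-abundance matrices over L/M/H feed-efficiency groups:
TMM normalization, 95%-quantile abundance filtering, a directional
generalized Mann-Whitney test against the stochastic orderings
``F_L <=st F_M <=st F_H`` (increasing) and its reverse, Benjamini-
Hochberg FDR, CAZy/KO aggregation, KEGG pathway completeness, and
one-sided hypergeometric (Fisher) pathway enrichment.

The directional statistic for one gene is the probabilistic index

    t_inc = P(X_L < X_M < X_H)
          = (1/(nL nM nH)) * sum over triples of
            [I(a<b) + 0.5 I(a=b)] [I(b<c) + 0.5 I(b=c)],

with 1/6 expectation under a continuous exchangeable null; p-values
come from group-label permutations (exhaustive when few enough
arrangements exist, Monte-Carlo with the +1 correction otherwise).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tmm_normalize",
    "filter_high_abundance",
    "gmw_statistics",
    "gmw_directional",
    "gmw_test_matrix",
    "bh_fdr",
    "aggregate_by_annotation",
    "pathway_completeness",
    "pathway_enrichment",
    "run_metagenome_stage",
]


# --------------------------------------------------------------------------
# TMM normalization
# --------------------------------------------------------------------------

def tmm_normalize(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values normalization of a genes x samples table.

    The reference is the sample whose upper-quartile (of library-scaled
    counts) is closest to the mean upper-quartile.  Per sample, the
    factor is the inverse-variance-weighted mean of log2 abundance
    ratios after trimming the most extreme 30% of log-ratios and 5% of
    average intensities; factors are rescaled to geometric mean 1.
    Normalized value = count / (library size * factor).
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    scaled = counts.div(lib, axis=1)
    uq = scaled.quantile(0.75, axis=0)
    ref = (uq - uq.mean()).abs().idxmin()
    y_r = counts[ref].to_numpy(dtype=float)
    n_r = float(lib[ref])

    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        y_s = counts[s].to_numpy(dtype=float)
        n_s = float(lib[s])
        ok = (y_s > 0) & (y_r > 0)
        if not ok.any():
            warnings.warn(f"no co-expressed genes between {s} and reference: factor 1")
            factors[s] = 1.0
            continue
        ys, yr = y_s[ok], y_r[ok]
        m = np.log2((ys / n_s) / (yr / n_r))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
        w = (n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr)
        n = m.size
        lo_m, hi_m = math.floor(n * logratio_trim), n - math.floor(n * logratio_trim)
        lo_a, hi_a = math.floor(n * abs_trim), n - math.floor(n * abs_trim)
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        keep = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        if not keep.any():
            warnings.warn(f"trimming removed all genes for sample {s}: factor 1")
            factors[s] = 1.0
            continue
        inv_var = 1.0 / w[keep]
        factors[s] = float(2 ** (np.sum(m[keep] * inv_var) / np.sum(inv_var)))
    f = pd.Series(factors).reindex(counts.columns)
    f = f / np.exp(np.log(f).mean())  # geometric mean 1
    normalized = counts.div(lib * f, axis=1)
    return f, normalized


def filter_high_abundance(
    normalized: pd.DataFrame, q: float = 0.95
) -> pd.DataFrame:
    """Keep genes whose total normalized abundance reaches the q-quantile
    (linear interpolation) of all gene totals."""
    if normalized.empty:
        raise ValueError("empty matrix")
    totals = normalized.sum(axis=1)
    thr = float(np.quantile(totals.to_numpy(), q))
    if totals.nunique() == 1:
        warnings.warn("all gene totals equal: every gene kept")
    return normalized.loc[totals >= thr]


# --------------------------------------------------------------------------
# directional generalized Mann-Whitney test
# --------------------------------------------------------------------------

def _pair_matrix(values: np.ndarray) -> np.ndarray:
    """C[g, i, j] = I(v_i < v_j) + 0.5 I(v_i = v_j) per gene."""
    v = values[:, :, None]
    u = values[:, None, :]
    return (v < u) + 0.5 * (v == u)


def _group_indicators(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (labels == "L").astype(float), (labels == "M").astype(float), (labels == "H").astype(float)


def _t_many(C: np.ndarray, IL: np.ndarray, IM: np.ndarray, IH: np.ndarray) -> np.ndarray:
    """t_inc for many permutations at once.

    C is (G, n, n); IL/IM/IH are (P, n) indicator matrices.  Returns (P, G).
    """
    G, n, _ = C.shape
    nL, nM, nH = IL[0].sum(), IM[0].sum(), IH[0].sum()
    # A[p, g, m] = sum_l IL[p, l] C[g, l, m]
    A = (IL @ C.transpose(1, 0, 2).reshape(n, G * n)).reshape(-1, G, n)
    # B[p, g, m] = sum_h C[g, m, h] IH[p, h]
    B = (C.reshape(G * n, n) @ IH.T).reshape(G, n, -1).transpose(2, 0, 1)
    t = np.einsum("pgm,pgm,pm->pg", A, B, IM)
    return t / (nL * nM * nH)


def gmw_statistics(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triple-ordering statistics t_inc, t_dec for each row of ``values``.

    ``labels`` contains 'L', 'M', 'H' per column.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    C = _pair_matrix(values)
    IL, IM, IH = (x[None, :] for x in _group_indicators(labels))
    t_inc = _t_many(C, IL, IM, IH)[0]
    t_dec = _t_many(C, IH, IM, IL)[0]
    return t_inc, t_dec


def _n_arrangements(nL: int, nM: int, nH: int) -> int:
    n = nL + nM + nH
    return math.comb(n, nL) * math.comb(n - nL, nM)


def gmw_test_matrix(
    values: np.ndarray | pd.DataFrame,
    labels,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 10_000,
) -> pd.DataFrame:
    """Directional generalized Mann-Whitney test for every row (gene).

    Exhaustive permutation p-values when the number of distinct
    label arrangements is at most ``exhaustive_limit``; otherwise
    Monte-Carlo with the +1 correction.  The reported ``direction`` is
    the alternative with the smaller p (``increasing`` = L<M<H).
    """
    df = values if isinstance(values, pd.DataFrame) else None
    V = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(pd.Series(labels).to_numpy())
    for g in ("L", "M", "H"):
        if not (labels == g).any():
            raise ValueError(f"group {g} is empty")
    nL = int((labels == "L").sum())
    nM = int((labels == "M").sum())
    nH = int((labels == "H").sum())
    n = len(labels)
    G = V.shape[0]
    C = _pair_matrix(V)
    IL0, IM0, IH0 = (x[None, :] for x in _group_indicators(labels))
    t_inc = _t_many(C, IL0, IM0, IH0)[0]
    t_dec = _t_many(C, IH0, IM0, IL0)[0]

    total = _n_arrangements(nL, nM, nH)
    if total <= exhaustive_limit:
        perms = np.zeros((total, n), dtype="U1")
        i = 0
        all_idx = set(range(n))
        for lset in combinations(range(n), nL):
            rest = sorted(all_idx - set(lset))
            for mset in combinations(rest, nM):
                row = np.full(n, "H", dtype="U1")
                row[list(lset)] = "L"
                row[list(mset)] = "M"
                perms[i] = row
                i += 1
        ILs = (perms == "L").astype(float)
        IMs = (perms == "M").astype(float)
        IHs = (perms == "H").astype(float)
        t_inc_perm = _t_many(C, ILs, IMs, IHs)
        t_dec_perm = _t_many(C, IHs, IMs, ILs)
        p_inc = (t_inc_perm >= t_inc[None, :] - 1e-12).mean(axis=0)
        p_dec = (t_dec_perm >= t_dec[None, :] - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        exceed_inc = np.zeros(G)
        exceed_dec = np.zeros(G)
        chunk = max(1, min(256, n_perm))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perm_labels = np.stack([rng.permutation(labels) for _ in range(m)])
            ILs = (perm_labels == "L").astype(float)
            IMs = (perm_labels == "M").astype(float)
            IHs = (perm_labels == "H").astype(float)
            exceed_inc += (_t_many(C, ILs, IMs, IHs) >= t_inc[None, :] - 1e-12).sum(axis=0)
            exceed_dec += (_t_many(C, IHs, IMs, ILs) >= t_dec[None, :] - 1e-12).sum(axis=0)
            done += m
        p_inc = (1.0 + exceed_inc) / (1.0 + n_perm)
        p_dec = (1.0 + exceed_dec) / (1.0 + n_perm)

    direction = np.where(p_inc <= p_dec, "increasing", "decreasing")
    p_min = np.minimum(p_inc, p_dec)
    out = pd.DataFrame(
        {
            "t_inc": t_inc,
            "t_dec": t_dec,
            "p_inc": p_inc,
            "p_dec": p_dec,
            "direction": direction,
            "p": p_min,
        }
    )
    if df is not None:
        out.index = df.index
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def gmw_directional(
    x_L, x_M, x_H, n_perm: int = 10_000, seed: int = 0
) -> pd.Series:
    """Directional test for a single gene given the three group samples."""
    x_L = np.asarray(x_L, dtype=float)
    x_M = np.asarray(x_M, dtype=float)
    x_H = np.asarray(x_H, dtype=float)
    for name, x in (("L", x_L), ("M", x_M), ("H", x_H)):
        if x.size == 0:
            raise ValueError(f"group {name} is empty")
    values = np.concatenate([x_L, x_M, x_H])[None, :]
    labels = np.repeat(["L", "M", "H"], [x_L.size, x_M.size, x_H.size])
    return gmw_test_matrix(values, labels, n_perm=n_perm, seed=seed).iloc[0]


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# annotation aggregation, completeness, enrichment
# --------------------------------------------------------------------------

def aggregate_by_annotation(
    normalized: pd.DataFrame, gene2ann: dict[str, str]
) -> tuple[pd.DataFrame, dict]:
    """Sum member-gene abundances per annotation label.

    Unannotated genes are excluded and counted in the report dict.
    """
    ann = pd.Series({g: gene2ann.get(g) for g in normalized.index})
    annotated = ann.dropna()
    report = {
        "n_genes": len(normalized),
        "n_annotated": int(len(annotated)),
        "coverage": float(len(annotated) / max(len(normalized), 1)),
    }
    if annotated.empty:
        return pd.DataFrame(columns=normalized.columns), report
    agg = normalized.loc[annotated.index].groupby(annotated).sum()
    agg.index.name = "annotation"
    return agg, report


def pathway_completeness(
    detected_kos: set[str], pathway2kos: dict[str, set[str]]
) -> tuple[pd.Series, dict]:
    """Fraction of each pathway's KOs detected, with median/IQR summary."""
    out = {}
    for pid, kos in pathway2kos.items():
        if not kos:
            warnings.warn(f"pathway {pid} has an empty KO set: skipped")
            continue
        out[pid] = len(detected_kos & set(kos)) / len(kos)
    series = pd.Series(out, name="completeness")
    if series.empty:
        return series, {"median": np.nan, "iqr_low": np.nan, "iqr_high": np.nan}
    q1, med, q3 = np.percentile(series.to_numpy(), [25, 50, 75])
    return series, {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3)}


def pathway_enrichment(
    significant_kos: set[str],
    pathway2kos: dict[str, set[str]],
    detected_kos: set[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of significant KOs per pathway.

    The universe is the set of detected KOs present in any pathway;
    ``p = P(X >= k)`` for ``X ~ Hypergeom(N=|universe|,
    K=|significant in universe|, n=|pathway in universe|)``, BH-adjusted
    at the given FDR.  Pathways disjoint from the universe are skipped.
    """
    union = set().union(*pathway2kos.values()) if pathway2kos else set()
    universe = union if detected_kos is None else (union & set(detected_kos))
    N = len(universe)
    K = len(set(significant_kos) & universe)
    rows = []
    for pid, kos in pathway2kos.items():
        in_u = set(kos) & universe
        if not in_u:
            continue
        n = len(in_u)
        k = len(set(significant_kos) & in_u)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": pid, "n_kos": n, "n_significant": k, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = out["q"] <= fdr
    return out.sort_values(["p", "pathway"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# end-to-end stage
# --------------------------------------------------------------------------

def run_metagenome_stage(
    gene_counts: pd.DataFrame,
    groups: pd.Series,
    annotation: dict,
    filter_q: float = 0.95,
    ko_sig_p: float = 0.1,
    fdr: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """TMM -> filter -> gene tests -> BH -> CAZy family tests -> KO tests
    -> pathway enrichment and completeness.

    ``annotation`` holds ``gene2ko``, ``gene2cazy``, ``pathway2kos``.
    Returns a dict of result tables and summaries.
    """
    groups = pd.Series(groups).loc[gene_counts.columns]
    labels = groups.to_numpy()
    factors, normalized = tmm_normalize(gene_counts)
    filtered = filter_high_abundance(normalized, q=filter_q)
    gene_res = gmw_test_matrix(filtered, labels, n_perm=n_perm, seed=seed)

    cazy_abund, cazy_report = aggregate_by_annotation(filtered, annotation["gene2cazy"])
    if len(cazy_abund):
        cazy_res = gmw_test_matrix(cazy_abund, labels, n_perm=n_perm, seed=seed + 1)
    else:
        cazy_res = pd.DataFrame()

    ko_abund, ko_report = aggregate_by_annotation(filtered, annotation["gene2ko"])
    if len(ko_abund):
        ko_res = gmw_test_matrix(ko_abund, labels, n_perm=n_perm, seed=seed + 2)
        significant_kos = set(ko_res.index[ko_res["p"] <= ko_sig_p])
    else:
        ko_res = pd.DataFrame()
        significant_kos = set()

    detected_kos = set(ko_abund.index) if len(ko_abund) else set()
    enrichment = pathway_enrichment(
        significant_kos, annotation["pathway2kos"], detected_kos=detected_kos, fdr=fdr
    )
    completeness, completeness_summary = pathway_completeness(
        detected_kos, annotation["pathway2kos"]
    )
    return {
        "tmm_factors": factors,
        "n_genes_filtered": len(filtered),
        "gene_results": gene_res,
        "cazy_results": cazy_res,
        "cazy_report": cazy_report,
        "ko_results": ko_res,
        "ko_report": ko_report,
        "significant_kos": significant_kos,
        "enrichment": enrichment,
        "completeness": completeness,
        "completeness_summary": completeness_summary,
    }
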