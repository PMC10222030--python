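"""Graphical lasso with EBIC, hub scores, modules, association statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microrei.network import (
    GraphicalLassoEBIC,
    asv_rei_coefficients,
    detect_modules,
    glasso,
    hub_rei_correlation,
    hub_scores,
    module_component_association,
    module_rei_stats,
    network_sparsity,
    pearson_test,
)
from conftest import planted_precision


def admm_glasso(S, lam, rho=1.0, iters=4000):
    """Independent penalized-likelihood optimizer (ADMM splitting)."""
    p = S.shape[0]
    Zm, U = np.eye(p), np.zeros((p, p))
    for _ in range(iters):
        w, V = np.linalg.eigh(rho * (Zm - U) - S)
        xi = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        X = V @ np.diag(xi) @ V.T
        M = X + U
        Z2 = np.sign(M) * np.maximum(np.abs(M) - lam / rho, 0.0)
        np.fill_diagonal(Z2, np.diag(M))
        U = U + X - Z2
        Zm = Z2
    return Zm


class TestGlasso:
    def test_matches_independent_optimizer_p3(self):
        rng = np.random.default_rng(1)
        Z = rng.multivariate_normal(
            np.zeros(3), [[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]], size=200
        )
        Z = (Z - Z.mean(0)) / Z.std(0)
        S = Z.T @ Z / len(Z)
        for lam in (0.05, 0.2):
            Om, _, _ = glasso(S, lam, max_iter=200, tol=1e-8)
            np.testing.assert_allclose(Om, admm_glasso(S, lam), atol=1e-4)

    def test_lambda_above_max_correlation_gives_diagonal(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(100, 6))
        Zs = (Z - Z.mean(0)) / Z.std(0)
        S = Zs.T @ Zs / 100
        lam_max = np.abs(S - np.diag(np.diag(S))).max()
        Om, _, _ = glasso(S, lam_max * 1.0001)
        off = Om - np.diag(np.diag(Om))
        assert np.abs(off).max() < 1e-10

    def test_edge_recovery_f1_on_planted_precision(self):
        Sig, Om_true, rng = planted_precision(p=20, n_edges=15, seed=3)
        Z = rng.multivariate_normal(np.zeros(20), Sig, size=500)
        fit = GraphicalLassoEBIC(n_lambda=100).fit(Z)
        true_edges = {
            (i, j)
            for i in range(20)
            for j in range(i + 1, 20)
            if abs(Om_true[i, j]) > 1e-6
        }
        est = {(i, j) for i, j, _ in fit.edges_}
        tp = len(est & true_edges)
        f1 = 2 * tp / (2 * tp + len(est - true_edges) + len(true_edges - est))
        assert f1 > 0.8

    def test_monotone_edge_inclusion_along_path(self):
        Sig, _, rng = planted_precision(p=10, n_edges=8, seed=5)
        Z = rng.multivariate_normal(np.zeros(10), Sig, size=400)
        fit = GraphicalLassoEBIC(n_lambda=40).fit(Z)
        grid = fit.ebic_grid_.sort_values("lambda", ascending=False)
        assert (np.diff(grid["n_edges"].to_numpy()) >= 0).all()

    def test_partial_correlation_invariants(self):
        Sig, _, rng = planted_precision(p=12, n_edges=10, seed=7)
        Z = rng.multivariate_normal(np.zeros(12), Sig, size=300)
        fit = GraphicalLassoEBIC(n_lambda=30).fit(Z)
        rho = fit.partial_corr_
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        assert np.abs(rho).max() <= 1.0 + 1e-9
        assert (np.diag(rho) == 0).all()
        assert 0.0 <= network_sparsity(fit) <= 1.0

    def test_rank_deficient_input_jittered_with_warning(self):
        rng = np.random.default_rng(8)
        low = rng.normal(size=(50, 3)) @ rng.normal(size=(3, 10))
        with pytest.warns(UserWarning, match="ridge jitter"):
            fit = GraphicalLassoEBIC(n_lambda=20).fit(low)
        assert np.isfinite(fit.precision_).all()


class TestHubScores:
    def test_complete_graph_all_ones(self):
        A = np.full((5, 5), 0.4)
        np.fill_diagonal(A, 0)
        np.testing.assert_allclose(hub_scores(A), 1.0)

    def test_star_graph(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 0.6
        h = hub_scores(A)
        assert h[0] == pytest.approx(1.0)
        np.testing.assert_allclose(h[1:], 1 / np.sqrt(3), atol=1e-9)

    def test_empty_graph_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty edge set"):
            h = hub_scores(np.zeros((4, 4)))
        assert (h == 0).all()


class TestReiCoefficients:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        ab = pd.DataFrame({"asv": x}, index=[f"s{i}" for i in range(30)])
        rei = pd.Series(2.0 * x + 5.0, index=ab.index)
        beta = asv_rei_coefficients(ab, rei)
        assert beta["asv"] == pytest.approx(2.0)

    def test_closed_form_cov_over_var(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 9.0])
        ab = pd.DataFrame({"a": x}, index=list("vwxyz"))
        beta = asv_rei_coefficients(ab, pd.Series(y, index=ab.index))
        expected = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
        assert beta["a"] == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        ab = pd.DataFrame({"a": [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="zero-variance"):
            beta = asv_rei_coefficients(ab, pd.Series([1.0, 2.0, 3.0], index=ab.index))
        assert np.isnan(beta["a"])

    def test_null_case_near_zero(self):
        rng = np.random.default_rng(10)
        ab = pd.DataFrame({"a": rng.normal(size=5000)},
                          index=[f"s{i}" for i in range(5000)])
        rei = pd.Series(rng.normal(size=5000), index=ab.index)
        beta = asv_rei_coefficients(ab, rei)
        assert abs(beta["a"]) < 0.05


class TestModules:
    def test_two_planted_blocks_perfect_recovery(self):
        rho = np.zeros((40, 40))
        rho[:20, :20] = 0.5
        rho[20:, 20:] = 0.5
        np.fill_diagonal(rho, 0)
        mods = detect_modules(rho, min_size=10)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, mods.to_numpy()) == 1.0
        assert set(mods.value_counts()[mods.value_counts() > 0].index) == {1, 2}

    def test_all_equal_correlations_one_module(self):
        rho = np.full((30, 30), 0.3)
        np.fill_diagonal(rho, 0)
        mods = detect_modules(rho, min_size=10)
        assert (mods == 1).all()

    def test_min_size_enforced(self):
        Sig, _, rng = planted_precision(p=30, n_edges=40, seed=11)
        Z = rng.multivariate_normal(np.zeros(30), Sig, size=200)
        fit = GraphicalLassoEBIC(n_lambda=20).fit(Z)
        mods = detect_modules(fit.partial_corr_, min_size=5)
        sizes = mods[mods > 0].value_counts()
        assert (sizes >= 5).all()

    def test_deterministic(self):
        rho = np.zeros((30, 30))
        rho[:15, :15] = 0.4
        rho[15:, 15:] = 0.4
        np.fill_diagonal(rho, 0)
        m1 = detect_modules(rho, min_size=10)
        m2 = detect_modules(rho, min_size=10)
        assert m1.equals(m2)


class TestAssociationStats:
    def test_pearson_closed_form(self):
        # r = 0.5, n = 27 -> t = 2.8868, p = 0.0080
        t = 0.5 * np.sqrt(25) / np.sqrt(1 - 0.25)
        assert t == pytest.approx(2.8868, abs=1e-4)
        p = 2 * stats.t.sf(t, df=25)
        assert p == pytest.approx(0.0080, abs=5e-4)
        # pearson_test matches the same closed form on constructed data
        rng = np.random.default_rng(12)
        x = rng.normal(size=10)
        y = 0.3 * x + rng.normal(size=10)
        r, pv = pearson_test(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref)
        assert pv == pytest.approx(p_ref)

    def test_perfect_relation(self):
        x = np.arange(10.0)
        r, p = pearson_test(x, 3 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_module_rei_stats_sign(self):
        rng = np.random.default_rng(13)
        n = 60
        score = rng.normal(size=n)
        Z = pd.DataFrame(
            {f"a{j}": score + rng.normal(size=n) * 0.3 for j in range(12)}
            | {f"b{j}": rng.normal(size=n) for j in range(12)},
            index=[f"s{i}" for i in range(n)],
        )
        modules = pd.Series([1] * 12 + [2] * 12, index=Z.columns)
        rei = pd.Series(-2.0 * score + rng.normal(size=n) * 0.5, index=Z.index)
        out = module_rei_stats(Z, modules, rei)
        mod1 = out[out["module"] == 1].iloc[0]
        assert mod1["pearson_r"] < -0.5 and mod1["p"] < 1e-4

    def test_hub_rei_correlation_ignores_nan_betas(self):
        hub = np.array([1.0, 0.5, 0.2, 0.1])
        beta = np.array([-2.0, -1.0, np.nan, 0.5])
        r, p = hub_rei_correlation(hub, beta)
        assert np.isfinite(r) and np.isfinite(p)

    def test_module_component_association_planted_shift(self):
        rng = np.random.default_rng(14)
        loadings = pd.DataFrame(
            [np.concatenate([rng.normal(3, 0.2, 15), rng.normal(0, 0.2, 15)])],
            index=["Arch1"], columns=[f"a{j}" for j in range(30)],
        )
        modules = pd.Series([1] * 15 + [2] * 15, index=loadings.columns)
        out = module_component_association(modules, loadings)
        assert out.iloc[0]["p"] < 1e-5

    def test_single_module_rejected(self):
        loadings = pd.DataFrame(np.ones((1, 10)), index=["Arch1"],
                                columns=[f"a{j}" for j in range(10)])
        modules = pd.Series([1] * 10, index=loadings.columns)
        with pytest.raises(ValueError, match="2 modules"):
            module_component_association(modules, loadings)


def test_planted_consortium_association_sign_recovered():
    """A module whose member abundances track a planted REI effect keeps
    the planted sign of association in nearly every replicate."""
    from microrei.simulate import CohortConfig, simulate_community

    hits = 0
    for seed in range(20):
        cfg = CohortConfig(
            n_animals=60, n_asvs=120, n_components=3, module_sizes=(15, 12, 10),
            component_effects=(6.0, 0.0, 0.0), rei_independent_sd=4.0, seed=seed,
        )
        counts, truth = simulate_community(cfg)
        rel = counts.div(counts.sum(axis=1), axis=0)
        members = rel.columns[truth.module_labels == 1]
        scaled = (rel - rel.mean()) / rel.std().replace(0, 1.0)
        modules = pd.Series(
            np.where(np.isin(rel.columns, members), 1, 0), index=rel.columns
        )
        rei = pd.Series(truth.rei_true, index=rel.index)
        out = module_rei_stats(scaled, modules, rei)
        hits += out.iloc[0]["pearson_r"] > 0
    assert hits >= 18
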