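"""TMM normalization, directional gMW test, FDR, aggregation, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from microrei import simulate as sim
from microrei.metagenome import (
    aggregate_by_annotation,
    bh_fdr,
    filter_high_abundance,
    gmw_directional,
    gmw_statistics,
    gmw_test_matrix,
    pathway_completeness,
    pathway_enrichment,
    run_metagenome_stage,
    tmm_normalize,
)


class TestTmm:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(40, size=150)
        counts = pd.DataFrame({s: col for s in "wxyz"})
        f, _ = tmm_normalize(counts)
        np.testing.assert_allclose(f.to_numpy(), 1.0)

    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(500, size=(500, 6)),
                              columns=list("abcdef"))
        _, base = tmm_normalize(counts)
        scaled = counts.copy()
        scaled["f"] = counts["f"] * 2
        _, doubled = tmm_normalize(scaled)
        assert np.abs(base.to_numpy() - doubled.to_numpy()).max() < 1e-6

    def test_factors_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.1, size=(300, 5)),
                              columns=list("abcde"))
        f, _ = tmm_normalize(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_normalize(counts)


class TestFilter:
    def test_hundred_distinct_totals_keep_five(self):
        rng = np.random.default_rng(3)
        normalized = pd.DataFrame(
            {"s1": np.arange(100.0), "s2": np.arange(100.0)[::-1] * 0 + 1}
        )
        kept = filter_high_abundance(normalized, q=0.95)
        assert len(kept) == 5

    def test_all_equal_totals_all_kept_with_warning(self):
        normalized = pd.DataFrame({"s1": np.ones(20), "s2": np.ones(20)})
        with pytest.warns(UserWarning, match="every gene kept"):
            kept = filter_high_abundance(normalized)
        assert len(kept) == 20

    def test_raising_q_never_grows_the_set(self):
        rng = np.random.default_rng(4)
        normalized = pd.DataFrame(rng.random((80, 3)))
        prev = None
        for q in (0.5, 0.7, 0.9, 0.95):
            kept = set(filter_high_abundance(normalized, q=q).index)
            if prev is not None:
                assert kept <= prev
            prev = kept


def brute_force_t(xL, xM, xH):
    w = lambda a, b: (a < b) + 0.5 * (a == b)
    t = 0.0
    for a in xL:
        for b in xM:
            for c in xH:
                t += w(a, b) * w(b, c)
    return t / (len(xL) * len(xM) * len(xH))


class TestGmwStatistic:
    def test_fully_ordered_groups_t_one(self):
        res = gmw_directional([1, 2], [3, 4], [5, 6], n_perm=100, seed=0)
        assert res["t_inc"] == 1.0

    def test_all_tied_quarter(self):
        res = gmw_directional([1, 1], [1, 1], [1, 1], n_perm=100, seed=0)
        assert res["t_inc"] == 0.25 and res["t_dec"] == 0.25

    def test_matches_cubic_brute_force_with_ties(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["L", "M", "H"], [6, 5, 8])
        V = rng.integers(0, 5, size=(25, 19)).astype(float)
        t_inc, t_dec = gmw_statistics(V, labels)
        for g in range(25):
            xL, xM, xH = V[g, :6], V[g, 6:11], V[g, 11:]
            assert t_inc[g] == pytest.approx(brute_force_t(xL, xM, xH), abs=1e-12)
            assert t_dec[g] == pytest.approx(brute_force_t(xH, xM, xL), abs=1e-12)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(6)
        labels = np.repeat(["L", "M", "H"], [5, 5, 5])
        V = rng.normal(size=(10, 15))
        t_inc, t_dec = gmw_statistics(V, labels)
        flipped = V[:, ::-1]
        labels_flipped = labels[::-1]
        t_inc2, _ = gmw_statistics(flipped, np.where(
            labels_flipped == "L", "H", np.where(labels_flipped == "H", "L", "M")))
        np.testing.assert_allclose(t_dec, t_inc2, atol=1e-12)

    def test_null_expectation_one_sixth(self):
        rng = np.random.default_rng(7)
        labels = np.repeat(["L", "M", "H"], [11, 10, 11])
        V = rng.normal(size=(2000, 32))
        t_inc, _ = gmw_statistics(V, labels)
        assert np.mean(t_inc) == pytest.approx(1 / 6, abs=0.005)


class TestGmwPvalues:
    def test_exhaustive_small_groups(self):
        # 2+2+2: 90 distinct arrangements, enumerated exactly
        res = gmw_directional([1, 2], [3, 4], [5, 6], n_perm=10, seed=0)
        # the fully ordered arrangement: t=1 attained only by the identity
        assert res["p_inc"] == pytest.approx(1 / 90)

    def test_type_i_error_near_alpha(self):
        rng = np.random.default_rng(8)
        labels = np.repeat(["L", "M", "H"], [11, 10, 11])
        V = rng.normal(size=(1000, 32))
        res = gmw_test_matrix(V, labels, n_perm=999, seed=1)
        rate = (res["p_inc"] <= 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_power_monotone_in_effect(self):
        labels = np.repeat(["L", "M", "H"], [11, 10, 11])
        shift = np.repeat([-1.0, 0.0, 1.0], [11, 10, 11])
        rng = np.random.default_rng(9)
        power = []
        for effect in (0.5, 1.0, 1.5):
            V = rng.normal(size=(300, 32)) + effect * shift
            res = gmw_test_matrix(V, labels, n_perm=499, seed=2)
            power.append((res["p_inc"] <= 0.05).mean())
        assert power[0] < power[1] < power[2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gmw_directional([], [1.0], [2.0])


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_in_sorted_order_and_at_least_p(self, ps):
        p = np.asarray(ps)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestAggregation:
    def test_bijective_map_is_identity(self):
        normalized = pd.DataFrame(
            np.arange(12.0).reshape(3, 4), index=["g1", "g2", "g3"],
            columns=list("abcd"),
        )
        agg, report = aggregate_by_annotation(
            normalized, {"g1": "K1", "g2": "K2", "g3": "K3"}
        )
        np.testing.assert_allclose(
            agg.loc[["K1", "K2", "K3"]].to_numpy(), normalized.to_numpy()
        )
        assert report["coverage"] == 1.0

    def test_partition_conserves_column_sums(self):
        rng = np.random.default_rng(10)
        normalized = pd.DataFrame(rng.random((10, 3)),
                                  index=[f"g{i}" for i in range(10)])
        mapping = {f"g{i}": f"K{i % 3}" for i in range(10)}
        agg, _ = aggregate_by_annotation(normalized, mapping)
        np.testing.assert_allclose(agg.sum(axis=0), normalized.sum(axis=0))

    def test_three_genes_one_ko_hand_sum(self):
        normalized = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]],
            index=["g1", "g2", "g3", "g4"], columns=["s1", "s2"],
        )
        agg, report = aggregate_by_annotation(
            normalized, {"g1": "K1", "g2": "K1", "g3": "K1"}
        )
        assert agg.loc["K1", "s1"] == 9.0 and agg.loc["K1", "s2"] == 12.0
        assert report["n_annotated"] == 3


class TestCompleteness:
    def test_closed_fractions(self):
        pathways = {"full": {"K1", "K2"}, "none": {"K8", "K9"},
                    "partial": {"K1", "K2", "K3", "K4", "K5", "K6", "K7", "K8"}}
        detected = {"K1", "K2", "K3"}
        comp, summary = pathway_completeness(detected, pathways)
        assert comp["full"] == 1.0
        assert comp["none"] == 0.0
        assert comp["partial"] == pytest.approx(0.375)

    def test_empty_pathway_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty KO set"):
            comp, _ = pathway_completeness({"K1"}, {"ok": {"K1"}, "bad": set()})
        assert "bad" not in comp.index


class TestEnrichment:
    def test_toy_hypergeometric_exact_value(self):
        # universe of 20 detected KOs (a background pathway covers them
        # all), 5 significant; a pathway of 4 containing 3 significant
        universe = {f"K{i}" for i in range(20)}
        significant = {f"K{i}" for i in range(5)}
        pathways = {"pw": {"K0", "K1", "K2", "K10"}, "background": universe}
        out = pathway_enrichment(significant, pathways, detected_kos=universe)
        row = out[out["pathway"] == "pw"].iloc[0]
        assert row["p"] == pytest.approx(155 / 4845)

    def test_no_significant_members_p_one(self):
        universe = {f"K{i}" for i in range(10)}
        out = pathway_enrichment({"K0"}, {"pw": {"K5", "K6"}},
                                 detected_kos=universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_everything_significant_p_one(self):
        universe = {f"K{i}" for i in range(10)}
        pathways = {"pw": {"K0", "K1"}}
        out = pathway_enrichment(universe, pathways, detected_kos=universe)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_tail_sum_equals_one_sided_fisher(self):
        universe = {f"K{i}" for i in range(30)}
        significant = {f"K{i}" for i in range(8)}
        pw = {f"K{i}" for i in range(5, 12)}
        pathways = {"pw": pw, "background": universe}
        out = pathway_enrichment(significant, pathways, detected_kos=universe)
        k = len(significant & pw)
        table = [
            [k, len(pw) - k],
            [len(significant) - k, 30 - len(pw) - len(significant) + k],
        ]
        _, fisher_p = stats.fisher_exact(table, alternative="greater")
        row = out[out["pathway"] == "pw"].iloc[0]
        assert row["p"] == pytest.approx(fisher_p, abs=1e-12)

    def test_disjoint_pathway_skipped(self):
        out = pathway_enrichment({"K1"}, {"pw": {"K99"}}, detected_kos={"K1", "K2"})
        assert out.empty


class TestEndToEnd:
    def test_planted_pathway_has_minimum_q(self):
        table, groups, ann, truth = sim.simulate_gene_matrix(
            n_genes=1000, effect=1.0, ordered_fraction=0.1, seed=5
        )
        res = run_metagenome_stage(table, groups, ann, n_perm=2000, seed=5)
        enr = res["enrichment"]
        assert enr.iloc[0]["pathway"] == "pw_planted"
        assert enr.iloc[0]["q"] <= 0.05

    def test_filter_arithmetic(self):
        table, groups, ann, _ = sim.simulate_gene_matrix(n_genes=400, seed=6)
        res = run_metagenome_stage(table, groups, ann, n_perm=199, seed=6)
        assert abs(res["n_genes_filtered"] - int(np.ceil(0.05 * 400))) <= 1

    def test_null_effect_rarely_yields_enriched_pathways(self):
        hits = 0
        for seed in range(10):
            table, groups, ann, _ = sim.simulate_gene_matrix(
                n_genes=300, effect=0.0, ordered_fraction=0.1, seed=seed
            )
            res = run_metagenome_stage(table, groups, ann, n_perm=499, seed=seed)
            enr = res["enrichment"]
            if len(enr) and enr["enriched"].any():
                hits += 1
        assert hits <= 1
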