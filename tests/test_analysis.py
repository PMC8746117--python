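"""Structure-function analyses: correlations, variability, activity flow,
cluster experiments, multiple testing."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from corticonn import analysis as an
from corticonn.connectome import CentralityResult, FLNMatrix, centrality, in_strength
from corticonn.synthetic import (
    SyntheticConnectomeParams,
    generate_fln,
    generate_var_truth,
    sample_var,
)


@pytest.fixture(scope="module")
def fln6():
    return generate_fln(SyntheticConnectomeParams(n_areas=6, density=1.0, seed=21))


def _table_from_matrices(fln, mats_by_sim):
    return an.build_edge_table(fln, {k: {"peak": m} for k, m in mats_by_sim.items()})


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert an.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert an.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_definitional_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 1000))
        xc, yc = x - x.mean(), y - y.mean()
        expect = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert an.pearson(x, y) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            an.pearson(np.ones(5), np.arange(5.0))


class TestFLNGPDCCorrelation:
    def test_identity_mapping_gives_r_one(self, fln6):
        mats = {k: fln6.values.copy() for k in range(3)}
        table = _table_from_matrices(fln6, mats)
        assert an.fln_gpdc_correlation(table, "pooled") == pytest.approx(1.0)
        per = an.fln_gpdc_correlation(table, "per-simulation")
        np.testing.assert_allclose(per.to_numpy(), 1.0)

    def test_permutation_null(self):
        fln = generate_fln(SyntheticConnectomeParams(n_areas=19, density=1.0, seed=23))
        rng = np.random.default_rng(6)
        off = ~np.eye(19, dtype=bool)
        g = np.zeros((19, 19))
        g[off] = rng.permutation(fln.values[off])
        table = _table_from_matrices(fln, {0: g, 1: g})
        r = an.fln_gpdc_correlation(table, "pooled")
        assert abs(r) < 0.1  # 342 edges: permuted weights decorrelate

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            an.fln_gpdc_correlation(pd.DataFrame(), "pooled")


class TestBootstrapEdges:
    def test_degenerate_identity(self, fln6):
        table = _table_from_matrices(fln6, {0: fln6.values})
        mean, ci, rs = an.bootstrap_edges(table, n_edges=20, n_boot=50, seed=0)
        np.testing.assert_allclose(rs, 1.0)

    def test_consistency_with_full_table(self, fln6):
        rng = np.random.default_rng(7)
        noisy = {
            k: np.clip(fln6.values * 2 + rng.normal(0, 0.05, (6, 6)), 0, None)
            for k in range(3)
        }
        table = _table_from_matrices(fln6, noisy)
        full_r = an.fln_gpdc_correlation(table, "pooled")
        mean, ci, rs = an.bootstrap_edges(table, n_edges=25, n_boot=400, seed=1)
        assert ci[0] - 0.1 < full_r < ci[1] + 0.1

    def test_deterministic(self, fln6):
        table = _table_from_matrices(fln6, {0: fln6.values})
        a = an.bootstrap_edges(table, n_edges=10, n_boot=20, seed=5)[2]
        b = an.bootstrap_edges(table, n_edges=10, n_boot=20, seed=5)[2]
        np.testing.assert_array_equal(a, b)

    def test_insufficient_edges_rejected(self, fln6):
        table = _table_from_matrices(fln6, {0: fln6.values})
        with pytest.raises(ValueError):
            an.bootstrap_edges(table, n_edges=100)


class TestCVAnalysis:
    def test_identical_simulations_flagged(self, fln6):
        table = _table_from_matrices(fln6, {k: fln6.values for k in range(3)})
        res = an.cv_analysis(table, centrality(fln6))
        assert np.all(res.cv == 0)
        assert all(np.isnan(v) for v in res.correlations.values())

    def test_cv_matches_two_pass_oracle(self, fln6):
        rng = np.random.default_rng(8)
        mats = {k: np.abs(fln6.values + rng.normal(0, 0.02, (6, 6))) for k in range(5)}
        for m in mats.values():
            np.fill_diagonal(m, 0.0)
        table = _table_from_matrices(fln6, mats)
        res = an.cv_analysis(table, centrality(fln6))
        stack = np.stack([mats[k] for k in range(5)])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(res.cv[off], sd[off] / mean[off], atol=1e-12)

    def test_needs_three_simulations(self, fln6):
        table = _table_from_matrices(fln6, {0: fln6.values, 1: fln6.values})
        with pytest.raises(ValueError):
            an.cv_analysis(table, centrality(fln6))


class TestEstimatedActivity:
    def test_single_source_term(self):
        v = np.array([[0, 1.0, 0], [0.5, 0, 0.2], [0.3, 0.3, 0]])
        fln = FLNMatrix(v)
        rates = np.array([1.0, 5.0, 2.0])
        act = an.estimated_activity(fln, np.zeros((3, 3)) + 1e-3, rates)
        assert act.p_fln[0] == pytest.approx(5.0)  # only FLN_01 * r_1

    def test_uniform_rates_factorize_to_in_strength(self, fln6):
        c = 4.0
        rates = np.full(6, c)
        act = an.estimated_activity(fln6, fln6.values, rates)
        np.testing.assert_allclose(act.p_fln, c * in_strength(fln6), rtol=1e-12)

    def test_gpdc_equal_fln_reproduces_structural_estimate(self, fln6):
        rates = np.linspace(1, 6, 6)
        act = an.estimated_activity(fln6, fln6.values, rates)
        np.testing.assert_allclose(act.p_fln, act.p_gpdc, rtol=1e-12)
        assert act.r_fln == pytest.approx(act.r_gpdc)


class TestWelchHolm:
    def test_identical_groups_not_rejected(self):
        g = [np.array([1.0, 2.0, 3.0])]
        out = an.welch_holm(g, [g[0].copy()])
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert not out["reject"].iloc[0]

    def test_welch_p_matches_definitional_formula(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 2, 15)
        out = an.welch_holm([a], [b])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = 2 * scipy.stats.t.sf(abs(t), df)
        assert out["t"].iloc[0] == pytest.approx(t, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_holm_arithmetic(self):
        # construct groups with known raw p-values is awkward; check the
        # step-down rule directly on the adjusted values instead
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests([0.01, 0.02, 0.03], 0.05, method="holm")
        assert reject.all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_holm_dominates_bonferroni(self, pvals):
        from statsmodels.stats.multitest import multipletests

        m = len(pvals)
        holm = multipletests(pvals, 0.05, method="holm")[0]
        bonf = np.asarray(pvals) < 0.05 / m
        assert np.all(holm[bonf])


@pytest.fixture(scope="module")
def var_signals(fln6):
    # VAR system whose lag couplings follow the connectome weights
    edges = [
        (j, i, 3.0 * fln6.values[i, j])
        for i in range(6)
        for j in range(6)
        if i != j
    ]
    tr = generate_var_truth(edges, 6, self_coupling=0.3)
    return {
        0: sample_var(tr, 6000, seed=31),
        1: sample_var(tr, 6000, seed=32),
    }


class TestClusterExperiment:
    def test_full_and_subset_agree_on_all_areas(self, fln6, var_signals):
        res = an.cluster_experiment(
            var_signals, fln6, sizes=[6], n_clusters=2,
            modes=("full", "subset"), p_max=3, seed=1,
        )
        piv = res.correlations.pivot_table(
            index=["simulation", "cluster"], columns="mode", values="r"
        )
        np.testing.assert_allclose(piv["full"], piv["subset"], atol=1e-10)
        assert res.tests["subset"]["t"].abs().iloc[0] < 1e-6

    def test_deterministic(self, fln6, var_signals):
        kw = dict(sizes=[4], n_clusters=3, modes=("subset",), p_max=3, seed=9)
        a = an.cluster_experiment(var_signals, fln6, **kw).correlations
        b = an.cluster_experiment(var_signals, fln6, **kw).correlations
        pd.testing.assert_frame_equal(a, b)

    def test_size_below_three_rejected(self, fln6, var_signals):
        with pytest.raises(ValueError):
            an.cluster_experiment(var_signals, fln6, sizes=[2], n_clusters=1)

    def test_mediated_chain_pairwise_degrades(self):
        # strong chain topology: pairwise conditioning inflates skip edges
        # and lowers the correlation with the true (chain) structure
        n = 6
        v = np.zeros((n, n))
        for k in range(n - 1):
            v[k + 1, k] = 0.5  # k -> k+1
        v[0, n - 1] = 1e-4  # keep row sums positive
        fln = FLNMatrix(v + 1e-6 * (~np.eye(n, dtype=bool)))
        edges = [(k, k + 1, 0.55) for k in range(n - 1)]
        tr = generate_var_truth(edges, n, self_coupling=0.2)
        sigs = {0: sample_var(tr, 12_000, seed=41)}
        res = an.cluster_experiment(
            sigs, fln, sizes=[4], n_clusters=12,
            modes=("subset", "pairwise"), p_max=3, seed=3,
            positive_fln_only=False,
        )
        g = res.correlations.groupby("mode")["r"].mean()
        assert g["pairwise"] < g["subset"]
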