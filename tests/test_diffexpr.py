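import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from microsig.diffexpr import (
    ModerationState,
    bh_adjust,
    contrast_de,
    de_genes,
    ebayes_moderate,
    fit_linear_models,
    run_voom_de,
    voom_transform,
    VoomFit,
)
from microsig.io import CountMatrix, DEResult
from microsig.simulate import SimConfig, simulate_counts


def _counts_from_matrix(mat: np.ndarray, groups: list[str]) -> CountMatrix:
    df = pd.DataFrame(
        mat, index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    )
    meta = pd.DataFrame({"subgroup": groups}, index=df.columns)
    return CountMatrix(df, meta)


def _manual_voomfit(y: np.ndarray, w: np.ndarray, groups: list[str]) -> VoomFit:
    idx = [f"g{i}" for i in range(y.shape[0])]
    cols = [f"s{j}" for j in range(y.shape[1])]
    return VoomFit(
        pd.DataFrame(y, index=idx, columns=cols),
        pd.DataFrame(w, index=idx, columns=cols),
        lambda x: np.ones_like(x),
        pd.Series(groups, index=cols),
    )


class TestVoomTransform:
    def test_flat_mean_variance_gives_near_uniform_weights(self):
        # log-counts Gaussian with variance independent of the mean
        rng = np.random.default_rng(0)
        means = rng.uniform(4, 12, 800)
        logc = means[:, None] + rng.normal(0, 0.3, (800, 8))
        cm = _counts_from_matrix(np.round(np.exp2(logc)).astype(int), ["a"] * 4 + ["b"] * 4)
        fit = voom_transform(cm, "subgroup")
        w = fit.weights.to_numpy()
        assert w.max() / w.min() < 1.5

    def test_duplicate_samples_keep_weights_finite(self):
        base = np.array([[10, 100, 1000, 50]]).T @ np.ones((1, 4), dtype=int)
        cm = _counts_from_matrix(base, ["a", "a", "b", "b"])
        fit = voom_transform(cm, "subgroup")
        assert np.isfinite(fit.weights.to_numpy()).all()
        assert (fit.weights.to_numpy() > 0).all()

    def test_decreasing_variance_trend_gives_increasing_weights(self):
        # dispersion shrinking with abundance -> high-count genes more precise
        rng = np.random.default_rng(1)
        means = np.sort(rng.uniform(3, 12, 600))
        sds = np.linspace(1.2, 0.05, 600)
        logc = means[:, None] + rng.normal(0, 1, (600, 10)) * sds[:, None]
        cm = _counts_from_matrix(np.round(np.exp2(logc)).astype(int), ["a"] * 5 + ["b"] * 5)
        fit = voom_transform(cm, "subgroup")
        mean_w = fit.weights.mean(axis=1)
        mean_y = fit.y.mean(axis=1)
        rho = stats.spearmanr(mean_y, mean_w).statistic
        assert rho > 0.95

    def test_single_sample_group_rejected(self):
        cm = _counts_from_matrix(np.ones((5, 3), dtype=int), ["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            voom_transform(cm, "subgroup")


class TestLinearModels:
    def test_unit_weights_recover_group_mean_difference(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(20, 6))
        fit = _manual_voomfit(y, np.ones_like(y), ["a"] * 3 + ["b"] * 3)
        lmf = fit_linear_models(fit)
        np.testing.assert_allclose(lmf.coef["a"], y[:, :3].mean(axis=1), rtol=1e-12)
        np.testing.assert_allclose(
            lmf.coef["a"] - lmf.coef["b"], y[:, :3].mean(axis=1) - y[:, 3:].mean(axis=1),
            rtol=1e-10, atol=1e-12,
        )

    def test_weighted_single_group_is_weighted_mean(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 5))
        w = rng.uniform(0.2, 5.0, size=(10, 5))
        fit = _manual_voomfit(y, w, ["a"] * 5)
        lmf = fit_linear_models(fit)
        expected = (w * y).sum(axis=1) / w.sum(axis=1)
        np.testing.assert_allclose(lmf.coef["a"], expected, rtol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(50, 9))
        w = rng.uniform(0.1, 10.0, size=(50, 9))
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        fit = _manual_voomfit(y, w, groups)
        lmf = fit_linear_models(fit)
        X = np.zeros((9, 3))
        for j, g in enumerate(groups):
            X[j, {"a": 0, "b": 1, "c": 2}[g]] = 1.0
        for g in range(50):
            W = np.diag(w[g])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[g])
            np.testing.assert_allclose(lmf.coef.iloc[g].to_numpy(), beta, atol=1e-8)
            r = y[g] - X @ beta
            s2 = (w[g] * r * r).sum() / (9 - 3)
            assert lmf.s2.iloc[g] == pytest.approx(s2, rel=1e-8)


class TestEBayes:
    def test_identical_variances_give_infinite_prior(self):
        s2 = pd.Series([2.0, 2.0, 2.0, 2.0])
        mod = ebayes_moderate(s2, 4.0)
        assert np.isinf(mod.df_prior)
        np.testing.assert_allclose(mod.s2_post, 2.0, rtol=1e-9)

    def test_grid_search_oracle_for_moment_matching(self):
        s2 = pd.Series([0.2, 1.0, 5.0, 25.0])
        d = 4.0
        mod = ebayes_moderate(s2, d)
        # independent brute-force: evar = trigamma(d0/2), scan a fine grid
        z = np.log(s2.to_numpy())
        e = z - special.digamma(d / 2) + np.log(d / 2)
        evar = e.var(ddof=1) - special.polygamma(1, d / 2)
        assert evar > 0
        grid = np.exp(np.linspace(np.log(0.01), np.log(1e4), 2_000_000))
        tri = special.polygamma(1, grid / 2)
        d0 = grid[np.argmin(np.abs(tri - evar))]
        s02 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
        assert mod.df_prior == pytest.approx(d0, rel=1e-4)
        assert mod.s2_prior == pytest.approx(s02, rel=1e-4)
        # posterior is the df-weighted compromise
        expected = (d0 * s02 + d * s2) / (d0 + d)
        np.testing.assert_allclose(mod.s2_post, expected, rtol=1e-4)

    def test_small_spread_collapses_to_infinite_prior(self):
        # (1, 2, 4) at 4 df has less spread than pure chi-square sampling
        # noise implies, so the moment equations have no finite solution:
        # the prior df is infinite and every posterior is the mean variance
        s2 = pd.Series([1.0, 2.0, 4.0])
        d = 4.0
        z = np.log(s2.to_numpy())
        e = z - special.digamma(d / 2) + np.log(d / 2)
        assert e.var(ddof=1) - special.polygamma(1, d / 2) < 0
        mod = ebayes_moderate(s2, d)
        assert np.isinf(mod.df_prior)
        np.testing.assert_allclose(mod.s2_post, s2.mean(), rtol=1e-12)

    def test_posterior_between_gene_and_prior_variance(self):
        rng = np.random.default_rng(5)
        s2 = pd.Series(rng.chisquare(4, 200) / 4)
        mod = ebayes_moderate(s2, 4.0)
        lo = np.minimum(s2, mod.s2_prior)
        hi = np.maximum(s2, mod.s2_prior)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()


class TestModeratedTLimits:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(30, 8))
        fit = _manual_voomfit(y, np.ones_like(y), ["a"] * 4 + ["b"] * 4)
        return fit_linear_models(fit)

    def test_zero_prior_df_recovers_ordinary_t(self, fitted):
        mod = ModerationState(fitted.s2, fitted.df_residual, 0.0, 1.0, fitted.s2)
        res = contrast_de(fitted, mod, "a", "b")
        # ordinary two-sample t with per-gene variance
        se = np.sqrt(fitted.s2 * (1 / 4 + 1 / 4))
        expected_t = (fitted.coef["a"] - fitted.coef["b"]) / se
        np.testing.assert_allclose(res.table["t"], expected_t, rtol=1e-10)
        expected_p = 2 * stats.t.sf(np.abs(expected_t), fitted.df_residual)
        np.testing.assert_allclose(res.table["pvalue"], expected_p, rtol=1e-10)

    def test_infinite_prior_df_pools_variances(self, fitted):
        s02 = float(np.exp(np.log(fitted.s2).mean()))
        mod = ModerationState(
            fitted.s2, fitted.df_residual, np.inf, s02,
            pd.Series(s02, index=fitted.s2.index),
        )
        res = contrast_de(fitted, mod, "a", "b")
        se = np.sqrt(s02 * 0.5)
        np.testing.assert_allclose(
            res.table["t"], (fitted.coef["a"] - fitted.coef["b"]) / se, rtol=1e-10
        )


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_step_up_enumeration(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_dominance_and_step_up_on_random_vector(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=1000)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        # independent step-up enumeration
        order = np.argsort(p)
        expected = np.empty_like(p)
        running = 1.0
        for rank in range(len(p), 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * len(p) / rank)
            expected[i] = running
        np.testing.assert_allclose(adj, expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDeGenes:
    def _res(self, table):
        return DEResult(table, ("x", "y"))

    def test_empty_table_gives_empty_sets(self):
        cols = ["log2fc", "t", "pvalue", "adj_pvalue", "mean_expr"]
        res = self._res(pd.DataFrame(columns=cols, dtype=float))
        assert de_genes(res) == (set(), set())

    def test_threshold_arithmetic(self):
        table = pd.DataFrame(
            {"log2fc": [2.1], "t": [5.0], "pvalue": [0.001], "adj_pvalue": [0.005],
             "mean_expr": [5.0]},
            index=["g1"],
        )
        up, down = de_genes(self._res(table), alpha=0.01, fc_threshold=4.0)
        assert up == {"g1"} and down == set()  # 2^2.1 ~ 4.29 > 4

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(8)
        n = 200
        table = pd.DataFrame(
            {
                "log2fc": rng.normal(0, 2, n),
                "t": rng.normal(0, 3, n),
                "pvalue": rng.uniform(0, 1, n),
                "mean_expr": rng.uniform(0, 10, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        table["adj_pvalue"] = np.minimum(table["pvalue"] * 2, 1.0)
        up, down = de_genes(self._res(table), alpha=0.2, fc_threshold=3.0)
        exp_up, exp_down = set(), set()
        for g, row in table.iterrows():
            if row.adj_pvalue < 0.2 and 2 ** row.log2fc > 3.0:
                exp_up.add(g)
            if row.adj_pvalue < 0.2 and 2 ** -row.log2fc > 3.0:
                exp_down.add(g)
        assert (up, down) == (exp_up, exp_down)


class TestStatisticalBehaviour:
    def test_null_counts_yield_few_discoveries(self):
        # no planted effect between two 8-sample groups
        cfg = SimConfig(
            n_genes=1500, n_core=0, n_contaminated=0, n_tissue_shared=0,
            n_macrophage=0, n_regional=0, n_microglia_per_region=8,
            n_macrophage_samples=2, n_tissue_samples=2,
        )
        rates = []
        for seed in range(5):
            cm, _ = simulate_counts(cfg, seed=seed)
            reg = cm.meta["region"]
            samples = list(reg.index[reg.isin(["cerebellum", "frontal_cortex"])])
            res = run_voom_de(cm.subset_samples(samples), reg.loc[samples],
                              ("cerebellum", "frontal_cortex"))
            rates.append((res.table["adj_pvalue"] < 0.01).mean())
        assert np.mean(rates) <= 0.02

    def test_planted_eightfold_genes_recovered(self):
        cfg = SimConfig(
            n_genes=2000, n_core=100, n_contaminated=0, n_tissue_shared=0,
            n_macrophage=0, n_regional=0,
        )
        cm, truth = simulate_counts(cfg, seed=42)
        src = cm.meta["cell_source"]
        samples = list(src.index[src.isin(["microglia", "alveolar_macrophage"])])
        res = run_voom_de(cm.subset_samples(samples), src.loc[samples],
                          ("microglia", "alveolar_macrophage"))
        up, _ = de_genes(res, alpha=0.01, fc_threshold=3.0)
        planted = set(truth.genes_of("core"))
        assert len(up & planted) / len(planted) >= 0.9
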