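import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canidmacro import (
    MODEL_NAMES,
    ModelSpec,
    aicc,
    aicc_weights,
    as_phylo_data,
    blomberg_k,
    fit_all_models,
    fit_model,
    fit_over_posterior,
    loglik,
    model_mean_cov,
    pagel_lambda_ml,
    pgls_compare,
    pgls_fit,
)
from canidmacro.simulate import SimulationConfig, simulate_posterior_sample, simulate_trait, simulate_tree
from canidmacro.trees import prune_to


def _specs(pdata):
    """One fully parameterized spec per model, scaled to the tree depth."""
    T = pdata.max_depth
    return {
        "BM": ModelSpec("BM", {"z0": 0.3, "sigma2": 0.7}),
        "OU": ModelSpec("OU", {"z0": 0.3, "sigma2": 0.7, "alpha": 1.2 / T}),
        "ACDC": ModelSpec("ACDC", {"z0": 0.3, "sigma2": 0.7, "r": 1.0 / T}),
        "Trend": ModelSpec("Trend", {"z0": 0.3, "sigma2": 0.7, "b_rate": 0.8 / T}),
        "Drift": ModelSpec("Drift", {"z0": 0.3, "sigma2": 0.7, "mu_drift": 0.2}),
        "Div": ModelSpec("Div", {"z0": 0.3, "sigma0_sq": 0.7, "psi": 0.05}),
    }


class TestModelMeanCov:
    def test_acdc_r_to_zero_is_bm(self, tree6):
        _, cov_bm = model_mean_cov(tree6, ModelSpec("BM", {"z0": 0, "sigma2": 1.3}))
        _, cov = model_mean_cov(tree6, ModelSpec("ACDC", {"z0": 0, "sigma2": 1.3, "r": 1e-12}))
        assert np.abs(cov - cov_bm).max() < 1e-8

    def test_ou_alpha_to_zero_is_bm(self, tree6):
        _, cov_bm = model_mean_cov(tree6, ModelSpec("BM", {"z0": 0, "sigma2": 2.0}))
        _, cov = model_mean_cov(tree6, ModelSpec("OU", {"z0": 0, "sigma2": 2.0, "alpha": 1e-10}))
        mask = cov_bm > 0
        assert np.abs(cov[mask] / cov_bm[mask] - 1.0).max() < 1e-6

    def test_div_psi_zero_is_bm(self, tree6):
        _, cov_bm = model_mean_cov(tree6, ModelSpec("BM", {"z0": 0, "sigma2": 0.9}))
        _, cov = model_mean_cov(tree6, ModelSpec("Div", {"z0": 0, "sigma0_sq": 0.9, "psi": 0.0}))
        assert np.allclose(cov, cov_bm)

    def test_div_two_tip_hand_integral(self):
        # cherry, both tips extant at depth 4: n(t) = 2 everywhere, so
        # V_ii = s0*4 + psi*8; shared time 0 -> V_ij = 0
        pd_ = as_phylo_data("(A:4,B:4);")
        _, cov = model_mean_cov(pd_, ModelSpec("Div", {"z0": 0, "sigma0_sq": 0.5, "psi": 0.25}))
        assert cov[0, 0] == pytest.approx(0.5 * 4 + 0.25 * 8)
        assert cov[0, 1] == pytest.approx(0.0)

    def test_div_hand_integral_with_extinction(self):
        # ((A:3,B:1):3,C:6): events: +1 at 0 (2 lineages), +1 at 3
        # (3 lineages), -1 at 4 (B dies, 2 lineages)
        pd_ = as_phylo_data("((A:3,B:1):3,C:6);")
        s0, psi = 1.0, 0.5
        _, cov = model_mean_cov(pd_, ModelSpec("Div", {"z0": 0, "sigma0_sq": s0, "psi": psi}))
        i = {l: k for k, l in enumerate(pd_.labels)}
        # A: depth 6: integral n = 2*3 + 3*1 + 2*2 = 13 -> 6 s0 + 13 psi
        assert cov[i["A"], i["A"]] == pytest.approx(6 * s0 + 13 * psi)
        # shared A,B time 3: integral n = 6 -> 3 s0 + 6 psi
        assert cov[i["A"], i["B"]] == pytest.approx(3 * s0 + 6 * psi)

    def test_trend_hand_formula(self):
        pd_ = as_phylo_data("((A:2,B:4):3,C:9);")
        s2, b = 1.5, 0.1
        _, cov = model_mean_cov(pd_, ModelSpec("Trend", {"z0": 0, "sigma2": s2, "b_rate": b}))
        i = {l: k for k, l in enumerate(pd_.labels)}
        # shared time of A,B is 3: s2*(3 + b*9/2)
        assert cov[i["A"], i["B"]] == pytest.approx(s2 * (3 + b * 4.5))
        assert cov[i["A"], i["A"]] == pytest.approx(s2 * (5 + b * 12.5))

    def test_drift_mean_structure(self, tree6):
        mean, _ = model_mean_cov(tree6, ModelSpec("Drift", {"z0": 1.0, "sigma2": 1.0, "mu_drift": 0.5}))
        assert np.allclose(mean, 1.0 + 0.5 * tree6.depths)

    def test_negative_trend_rate_rejected(self, tree6):
        bad = -2.0 / tree6.max_depth
        with pytest.raises(ValueError, match="Trend rate"):
            model_mean_cov(tree6, ModelSpec("Trend", {"z0": 0, "sigma2": 1, "b_rate": bad}))

    def test_ou_covariance_closed_form_two_tips(self):
        # non-ultrametric cherry: exact exponential covariance
        pd_ = as_phylo_data("(A:2,B:5);")
        a, s2 = 0.3, 1.7
        _, cov = model_mean_cov(pd_, ModelSpec("OU", {"z0": 0, "sigma2": s2, "alpha": a}))
        assert cov[0, 0] == pytest.approx(s2 / (2 * a) * (1 - np.exp(-2 * a * 2)))
        assert cov[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestLoglik:
    def test_matches_dense_mvn_oracle_all_models(self, tree6, rng):
        """Cholesky-based likelihood equals explicit inverse/determinant."""
        x = pd.Series(rng.normal(size=6), index=list(tree6.labels))
        for name, spec in _specs(tree6).items():
            mean, cov = model_mean_cov(tree6, spec)
            ll = loglik(tree6, x, spec)
            r = x.to_numpy() - mean
            dense = -0.5 * (
                6 * np.log(2 * np.pi)
                + np.log(np.linalg.det(cov))
                + r @ np.linalg.inv(cov) @ r
            )
            assert ll == pytest.approx(dense, abs=1e-9), name

    def test_boundary_parameters_reproduce_bm(self, tree6, rng):
        x = pd.Series(rng.normal(size=6), index=list(tree6.labels))
        bm = loglik(tree6, x, ModelSpec("BM", {"z0": 0.4, "sigma2": 1.1}))
        boundary = {
            "OU": {"z0": 0.4, "sigma2": 1.1, "alpha": 1e-12},
            "ACDC": {"z0": 0.4, "sigma2": 1.1, "r": 0.0},
            "Trend": {"z0": 0.4, "sigma2": 1.1, "b_rate": 0.0},
            "Drift": {"z0": 0.4, "sigma2": 1.1, "mu_drift": 0.0},
            "Div": {"z0": 0.4, "sigma0_sq": 1.1, "psi": 0.0},
        }
        for name, params in boundary.items():
            assert loglik(tree6, x, ModelSpec(name, params)) == pytest.approx(bm, abs=1e-6), name

    def test_two_tip_closed_form(self):
        pd_ = as_phylo_data("(A:4,B:9);")
        x = pd.Series([1.0, -0.5], index=["A", "B"])
        spec = ModelSpec("BM", {"z0": 0.2, "sigma2": 0.8})
        expected = stats.norm.logpdf(1.0, 0.2, np.sqrt(0.8 * 4)) + stats.norm.logpdf(
            -0.5, 0.2, np.sqrt(0.8 * 9)
        )
        assert loglik(pd_, x, spec) == pytest.approx(expected, abs=1e-12)

    def test_singular_covariance_reports_duplicates(self):
        pd_ = as_phylo_data("((A:0.0,B:0.0):5,C:5);")
        x = pd.Series([1.0, 1.0, 0.0], index=["A", "B", "C"])
        with pytest.raises(np.linalg.LinAlgError, match="duplicate"):
            loglik(pd_, x, ModelSpec("BM", {"z0": 0, "sigma2": 1}))


class TestFitModel:
    def test_bm_closed_form_mles(self, bd_tree100, rng):
        pdata = as_phylo_data(bd_tree100)
        x = simulate_trait(pdata, ModelSpec("BM", {"z0": 0.5, "sigma2": 0.3}), 7)
        fit = fit_model(pdata, x, "BM")
        C = pdata.C
        Cinv = np.linalg.inv(C)
        one = np.ones(pdata.n)
        xv = x.reindex(list(pdata.labels)).to_numpy()
        z0 = (one @ Cinv @ xv) / (one @ Cinv @ one)
        s2 = (xv - z0) @ Cinv @ (xv - z0) / pdata.n
        assert fit.params["z0"] == pytest.approx(z0, abs=1e-6)
        assert fit.params["sigma2"] == pytest.approx(s2, rel=1e-6)

    def test_nesting_loglik_ordering(self, bd_tree60):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        for seed in (0, 1, 2):
            x = simulate_trait(pdata, ModelSpec("BM", {"z0": 0, "sigma2": 0.1}), seed)
            fits = {f.name: f for f in fit_all_models(pdata, x)}
            for name in ("OU", "ACDC", "Trend", "Drift", "Div"):
                assert fits[name].loglik >= fits["BM"].loglik - 1e-8, (name, seed)

    def test_acdc_vs_bm_delta_bounded_under_bm_truth(self, bd_tree60):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        x = simulate_trait(pdata, ModelSpec("BM", {"z0": 0, "sigma2": 0.1}), 3)
        bm = fit_model(pdata, x, "BM")
        ac = fit_model(pdata, x, "ACDC")
        assert ac.loglik >= bm.loglik
        assert (bm.aicc - ac.aicc) <= 2 * ac.k

    def test_weights_attached_and_sum_to_one(self, bd_tree60, bm_trait60):
        tree, _ = bd_tree60
        fits = fit_all_models(tree, bm_trait60)
        assert sum(f.weight for f in fits) == pytest.approx(1.0)
        for f in fits:
            # stored AICc consistent with loglik/k/n
            assert f.aicc == pytest.approx(aicc(f.loglik, f.k, f.n), abs=1e-10)

    def test_too_few_tips_rejected(self):
        pd_ = as_phylo_data("((A:1,B:2):1,C:3);")
        x = pd.Series([0.0, 1.0, 2.0], index=["A", "B", "C"])
        with pytest.raises(ValueError, match="n >= k"):
            fit_model(pd_, x, "OU")


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-10.0, 2, 20) == pytest.approx(20 + 4 + 12 / 17)

    def test_single_model_weight_one(self):
        _, w = aicc_weights([123.4])
        assert w[0] == pytest.approx(1.0)

    def test_weights_from_loglik_k_pairs(self):
        a, w = aicc_weights(fits=[(-10.0, 2), (-9.0, 3)], n=20)
        assert w.sum() == pytest.approx(1.0)
        assert a[0] == pytest.approx(aicc(-10.0, 2, 20))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aicc_weights([])


class TestPagelLambda:
    def test_lambda_maximizes_profile_on_grid(self, bd_tree60, bm_trait60):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        res = pagel_lambda_ml(pdata, bm_trait60)
        from canidmacro.comparative import _gls_profile

        ones = np.ones((pdata.n, 1))
        xv = bm_trait60.reindex(list(pdata.labels)).to_numpy()
        for lam in np.arange(0, 1.001, 0.01):
            ll, _, _ = _gls_profile(pdata.lambda_cov(lam), ones, xv)
            assert res.loglik >= ll - 1e-8

    def test_bm_recovery_and_permutation_destruction(self, yule_tree128, rng):
        pdata = as_phylo_data(yule_tree128)
        lams, lams_perm = [], []
        for i in range(20):
            x = simulate_trait(pdata, ModelSpec("BM", {"z0": 0, "sigma2": 1}), 500 + i)
            lams.append(pagel_lambda_ml(pdata, x).lambda_)
            xp = pd.Series(x.to_numpy()[rng.permutation(pdata.n)], index=x.index)
            lams_perm.append(pagel_lambda_ml(pdata, xp).lambda_)
        assert np.median(lams) >= 0.9
        assert np.median(lams_perm) <= 0.1

    def test_degenerate_trait_rejected(self, tree6):
        x = pd.Series(np.ones(6), index=list(tree6.labels))
        with pytest.raises(ValueError, match="degenerate"):
            pagel_lambda_ml(tree6, x)


class TestBlombergK:
    def test_star_tree_k_is_one_for_any_trait(self, rng):
        star = as_phylo_data("(" + ",".join(f"s{i}:2.5" for i in range(10)) + ");")
        for seed in range(3):
            x = pd.Series(np.random.default_rng(seed).normal(size=10),
                          index=[f"s{i}" for i in range(10)])
            res = blomberg_k(star, x, n_perm=9, seed=0)
            assert res.K == pytest.approx(1.0, abs=1e-10)

    def test_permutation_floor(self, bd_tree60, bm_trait60):
        tree, _ = bd_tree60
        res = blomberg_k(tree, bm_trait60, n_perm=999, seed=0)
        assert res.p >= 1.0 / 1000.0

    def test_matches_direct_formula(self, bd_tree60, bm_trait60):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        res = blomberg_k(pdata, bm_trait60, n_perm=1, seed=0)
        C = pdata.C
        Ci = np.linalg.inv(C)
        one = np.ones(pdata.n)
        xv = bm_trait60.reindex(list(pdata.labels)).to_numpy()
        a = (one @ Ci @ xv) / (one @ Ci @ one)
        r = xv - a
        K = ((r @ r) / (r @ Ci @ r)) / ((np.trace(C) - pdata.n / (one @ Ci @ one)) / (pdata.n - 1))
        assert res.K == pytest.approx(K, rel=1e-12)


class TestPgls:
    def test_lambda_zero_equals_ols_oracle(self, bd_tree60, rng):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        X = pd.DataFrame({"x": rng.normal(size=pdata.n)}, index=list(pdata.labels))
        y = pd.Series(1 + 2 * X["x"] + rng.normal(size=pdata.n), index=X.index)
        fit = pgls_fit(pdata, y, X, lambda_mode=0.0)
        Xd = np.column_stack([np.ones(pdata.n), X["x"].to_numpy()])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y.to_numpy())
        assert np.abs(fit.params.to_numpy() - beta).max() < 1e-8

    def test_bm_residual_slope_recovery(self, bd_tree100, rng):
        pdata = as_phylo_data(bd_tree100)
        x = pd.Series(rng.normal(size=pdata.n), index=list(pdata.labels))
        resid = simulate_trait(pdata, ModelSpec("BM", {"z0": 0, "sigma2": 0.3}), 17)
        y = 1.0 + 2.0 * x + resid
        fit = pgls_fit(pdata, y, pd.DataFrame({"x": x}), lambda_mode=1.0)
        assert abs(fit.params["x"] - 2.0) < 3 * fit.bse["x"]

    def test_perfect_fit_flagged_not_crashed(self, bd_tree60):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        x = pd.Series(np.linspace(0, 1, pdata.n), index=list(pdata.labels))
        y = 3.0 + 2.0 * x
        with pytest.warns(UserWarning, match="perfect fit"):
            fit = pgls_fit(pdata, y, pd.DataFrame({"x": x}), lambda_mode=0.0)
        assert fit.perfect_fit
        assert fit.params["x"] == pytest.approx(2.0)

    def test_collinear_predictors_rejected(self, bd_tree60, rng):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        x = rng.normal(size=pdata.n)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=list(pdata.labels))
        y = pd.Series(rng.normal(size=pdata.n), index=X.index)
        with pytest.raises(ValueError, match="collinear"):
            pgls_fit(pdata, y, X)

    def test_compare_reports_three_modes_with_weights(self, bd_tree60, bm_trait60, rng):
        tree, _ = bd_tree60
        pdata = as_phylo_data(tree)
        X = pd.DataFrame({"x": rng.normal(size=pdata.n)}, index=list(pdata.labels))
        y = bm_trait60 + 0.5 * X["x"]
        table = pgls_compare(pdata, y, X)
        assert set(table["model"]) == {"ml", "brownian", "null"}
        assert table["AICw"].sum() == pytest.approx(1.0)


class TestFitOverPosterior:
    def test_identical_trees_give_single_tree_weights(self, bd_tree60, bm_trait60):
        tree, _ = bd_tree60
        import dendropy

        trees = dendropy.TreeList([tree.clone(depth=1) for _ in range(3)],
                                  taxon_namespace=tree.taxon_namespace)
        summ = fit_over_posterior(trees, bm_trait60, models=("BM", "OU", "Drift"))
        single = {f.name: f.weight for f in fit_all_models(tree, bm_trait60, ("BM", "OU", "Drift"))}
        for name, w in summ.median_weights.items():
            assert w == pytest.approx(single[name], abs=1e-10)

    def test_pruning_consistency(self, bd_tree60, bm_trait60):
        """Fitting on a pruned clade equals fitting the subtree directly."""
        tree, history = bd_tree60
        clade = list(history.table.loc[history.table["subfamily"] == "subfamily_A", "species"])
        if len(clade) < 6:
            clade = list(history.table["species"][:10])
        sub = prune_to(tree, clade)
        trait = bm_trait60.loc[sorted(clade)]
        direct = {f.name: f.weight for f in fit_all_models(sub, trait, ("BM", "Drift"))}
        import dendropy

        summ = fit_over_posterior(
            dendropy.TreeList([tree], taxon_namespace=tree.taxon_namespace),
            bm_trait60, models=("BM", "Drift"), species=clade,
        )
        for name, w in summ.median_weights.items():
            assert w == pytest.approx(direct[name], abs=1e-8)

    def test_posterior_recovery_strong_drift(self, bd_tree100):
        pdata = as_phylo_data(bd_tree100)
        T = pdata.max_depth
        x = simulate_trait(
            bd_tree100, ModelSpec("Drift", {"z0": 0, "sigma2": 1.0, "mu_drift": 4.0 / np.sqrt(T)}), 5
        )
        post = simulate_posterior_sample(bd_tree100, 10, jitter_sd=0.1, seed=3)
        summ = fit_over_posterior(post, x)
        assert summ.median_weights.idxmax() == "Drift"
        assert (summ.weights.sum(axis=1) - 1.0).abs().max() < 1e-9

    def test_trees_missing_most_species_skipped(self, bd_tree60, bm_trait60):
        tree, history = bd_tree60
        few = list(history.table["species"][:10])
        small = prune_to(tree, few)
        import dendropy

        trees = dendropy.TreeList([small, tree.clone(depth=1)], taxon_namespace=tree.taxon_namespace)
        with pytest.warns(UserWarning):
            summ = fit_over_posterior(trees, bm_trait60, models=("BM",))
        assert summ.n_trees == 1
        assert summ.skipped == [0]
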