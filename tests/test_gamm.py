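"""Stacked mixed model: stacking, VIF, spline basis, (RE)ML engine.

The GLS oracle here is a deliberately naive dense-matrix implementation
(explicit V = sigma2 I + sigma2_site Z Z', slogdet, full solve) kept
independent of the package's Woodbury-profiled engine.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sciopt
from scipy import stats

from musselshape import synth
from musselshape.gamm import (
    FormulaSpec,
    GammError,
    LongShapeTable,
    VarianceStructure,
    compare_models,
    effect_sizes,
    env_pca,
    fit_gamm,
    natural_cubic_basis,
    predict_with_ci,
    stack_scores,
    vif,
)


# ---------------------------------------------------------------------------
# dense GLS oracle


def dense_reml_oracle(y, X, site_codes):
    """Brute-force random-intercept GLS: dense V, profile nothing."""
    n, p = X.shape
    q = site_codes.max() + 1
    Z = np.zeros((n, q))
    Z[np.arange(n), site_codes] = 1.0

    def neg_reml(params):
        s2, s2_site = np.exp(params)
        V = s2 * np.eye(n) + s2_site * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        _, ld_v = np.linalg.slogdet(V)
        _, ld_x = np.linalg.slogdet(XtViX)
        return float(
            0.5 * (ld_v + ld_x + r @ Vi @ r + (n - p) * np.log(2 * np.pi))
        )

    res = sciopt.minimize(neg_reml, [0.0, -1.0], method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    s2, s2_site = np.exp(res.x)
    V = s2 * np.eye(n) + s2_site * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return beta, s2, s2_site


class TestStacking:
    def test_row_count_and_standardization(self):
        rng = np.random.default_rng(0)
        env = synth.generate_environment(5, seed=0)
        ids = [f"s{i}" for i in range(100)]
        specimens = pd.DataFrame(
            {
                "specimen_id": ids,
                "site_id": rng.choice(env.site_id, 100),
                "length": rng.uniform(25, 81, 100),
            }
        )
        scores = rng.normal(size=(100, 8)) * [5, 4, 3, 2, 1, 1, 1, 1]
        table = stack_scores(scores, ids, specimens, env, k_pcs=5)
        assert len(table.data) == 500
        for pc, block in table.data.groupby("pc"):
            assert block.shape_var.mean() == pytest.approx(0.0, abs=1e-12)
            assert block.shape_var.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_join_matches_brute_force_merge(self):
        rng = np.random.default_rng(1)
        env = synth.generate_environment(4, seed=1)
        ids = [f"s{i}" for i in range(30)]
        specimens = pd.DataFrame(
            {
                "specimen_id": ids,
                "site_id": rng.choice(env.site_id, 30),
                "length": rng.uniform(25, 81, 30),
            }
        )
        scores = rng.normal(size=(30, 5))
        table = stack_scores(scores, ids, specimens, env, k_pcs=3)
        row = table.data.query("specimen_id == 's7' and pc == 'PC2'").iloc[0]
        site = specimens.set_index("specimen_id").loc["s7", "site_id"]
        assert row.temperature == pytest.approx(
            env.set_index("site_id").loc[site, "temperature"]
        )
        z = (scores[:, 1] - scores[:, 1].mean()) / scores[:, 1].std(ddof=1)
        assert row.shape_var == pytest.approx(z[7], abs=1e-12)

    def test_missing_environment_named_error(self):
        env = synth.generate_environment(3, seed=2)
        specimens = pd.DataFrame(
            {"specimen_id": ["a", "b"], "site_id": ["S01", "S99"], "length": [30, 40]}
        )
        with pytest.raises(GammError, match="S99"):
            stack_scores(np.zeros((2, 5)), ["a", "b"], specimens, env)


class TestVif:
    def test_orthogonal_covariates_unit_vif(self):
        n = 16
        X = pd.DataFrame(
            {
                "a": np.tile([1.0, -1.0], n // 2),
                "b": np.repeat([1.0, -1.0], n // 2),
                "c": np.sin(np.arange(n)),
            }
        )
        X["a"], X["b"] = X.a - X.a.mean(), X.b - X.b.mean()
        table = vif(X[["a", "b"]])
        np.testing.assert_allclose(table.vif, 1.0, atol=1e-10)

    def test_duplicated_covariate_infinite(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=10)})
        X["b"] = X.a
        X["c"] = rng.normal(size=10)
        table = vif(X).set_index("covariate")
        assert np.isinf(table.loc["a", "vif"])
        assert table.loc["a", "collinear"]

    def test_matches_brute_force_r_squared(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=["t", "s", "c"])
        X["s"] += 0.8 * X["t"]
        table = vif(X).set_index("covariate")
        for c in X.columns:
            others = X.drop(columns=c)
            A = np.column_stack([np.ones(len(X)), others])
            beta, *_ = np.linalg.lstsq(A, X[c], rcond=None)
            resid = X[c] - A @ beta
            r2 = 1 - (resid**2).sum() / ((X[c] - X[c].mean()) ** 2).sum()
            assert table.loc[c, "vif"] == pytest.approx(1 / (1 - r2), abs=1e-10)


class TestEnvPca:
    def test_perfectly_correlated_pair_single_component(self):
        X = pd.DataFrame({"t": np.arange(8.0)})
        X["s"] = 2 * X.t + 1
        out = env_pca(X)
        assert out.pct_variance[0] == pytest.approx(100.0)

    def test_loading_sign_convention(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["t", "s", "c"])
        out = env_pca(X)
        for col in out.loadings.columns:
            load = out.loadings[col].to_numpy()
            assert load[np.argmax(np.abs(load))] > 0

    def test_constructed_structure_recovered(self):
        # temperature and salinity share a positive latent factor,
        # chl-a loads against it
        rng = np.random.default_rng(6)
        latent = rng.normal(size=20)
        X = pd.DataFrame(
            {
                "temperature": latent + 0.1 * rng.normal(size=20),
                "salinity": latent + 0.1 * rng.normal(size=20),
                "chla": -latent + 0.1 * rng.normal(size=20),
            }
        )
        out = env_pca(X)
        l1 = out.loadings["enviro-PC1"]
        # orient so the temperature loading is positive (overall sign of a
        # loading is conventional); the structure is what matters
        l1 = l1 * np.sign(l1["temperature"])
        assert l1["temperature"] > 0 and l1["salinity"] > 0 and l1["chla"] < 0
        assert l1["temperature"] == pytest.approx(l1["salinity"], abs=0.05)
        assert out.pct_variance[0] > 90

    def test_fewer_sites_than_covariates_rejected(self):
        X = pd.DataFrame(np.random.default_rng(7).normal(size=(2, 3)))
        with pytest.raises(GammError, match="fewer sites"):
            env_pca(X)


class TestSplineBasis:
    def test_reproduces_constants_and_hits_knots(self):
        knots = np.array([0.0, 1.0, 3.0])
        x = np.linspace(-0.5, 3.5, 41)
        B = natural_cubic_basis(x, knots)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
        Bk = natural_cubic_basis(knots, knots)
        np.testing.assert_allclose(Bk, np.eye(3), atol=1e-12)

    def test_linear_extrapolation_outside_knots(self):
        knots = np.array([0.0, 1.0, 2.0])
        B = natural_cubic_basis(np.array([-2.0, -1.0, 3.0, 4.0]), knots)
        # second differences along an extrapolated ray are zero
        left = natural_cubic_basis(np.array([-3.0, -2.0, -1.0]), knots)
        assert np.abs(np.diff(left, n=2, axis=0)).max() < 1e-9
        assert np.all(np.isfinite(B))


class TestEngine:
    def test_matches_dense_gls_oracle(self):
        # identity variance, no smooths, 3 sites
        env = synth.generate_environment(3, seed=8)
        tab = synth.simulate_long_table(
            n_specimens=30, k_pcs=2, env=env,
            length_slopes=[0.3, -0.1], sigma_site=0.4, seed=8,
        )
        formula = FormulaSpec(smooth_terms=(), linear_terms=("length",))
        fit = fit_gamm(tab, formula, VarianceStructure("identity"), "REML")
        df = tab.data
        y = df.shape_var.to_numpy()
        X = fit.design.build(df)
        codes = pd.Categorical(df.site_id).codes
        beta, s2, s2_site = dense_reml_oracle(y, X, codes)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)
        assert fit.sigma2 == pytest.approx(s2, abs=1e-6)
        assert fit.sigma2_site == pytest.approx(s2_site, abs=1e-6)

    def test_close_to_statsmodels_mixedlm(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        tab = synth.simulate_long_table(
            n_specimens=60, length_slopes=[0.4, 0, 0, 0, 0], sigma_site=0.5, seed=7
        )
        fit = fit_gamm(
            tab, FormulaSpec(smooth_terms=(), linear_terms=("length",)),
            VarianceStructure("identity"), "REML",
        )
        df = tab.data.copy()
        df["lc"] = df.length - df.length.mean()
        m = smf.mixedlm("shape_var ~ 0 + pc + lc:pc", df, groups=df.site_id).fit(
            reml=True
        )
        slopes_ours = fit.beta[[fit.design.column_names.index(f"length:PC{j}") for j in range(1, 6)]]
        slopes_sm = m.params[[f"lc:pc[PC{j}]" for j in range(1, 6)]].to_numpy()
        np.testing.assert_allclose(slopes_ours, slopes_sm, atol=1e-3)

    def test_loglik_nesting_monotone(self):
        tab = synth.simulate_long_table(
            n_specimens=60, salinity_slopes={"PC1": 0.05}, sigma_site=0.3, seed=9
        )
        reduced = fit_gamm(
            tab, FormulaSpec(smooth_terms=(), linear_terms=("length",)), method="ML"
        )
        full = fit_gamm(
            tab,
            FormulaSpec(smooth_terms=("salinity",), linear_terms=("length",)),
            method="ML",
        )
        assert full.loglik >= reduced.loglik - 1e-6

    def test_equivariance_to_covariate_rescaling(self):
        tab = synth.simulate_long_table(
            n_specimens=50, length_slopes={"PC1": 0.3}, sigma_site=0.2, seed=10
        )
        fit1 = fit_gamm(tab, method="REML")
        data2 = tab.data.copy()
        data2["length"] = data2["length"] / 10.0  # cm instead of mm
        fit2 = fit_gamm(LongShapeTable(data2), method="REML")
        i = fit1.design.column_names.index("length:PC1")
        assert fit2.beta[i] == pytest.approx(10.0 * fit1.beta[i], rel=1e-5)
        fitted1 = fit1.design.build(tab.data) @ fit1.beta
        fitted2 = fit2.design.build(data2) @ fit2.beta
        np.testing.assert_allclose(fitted1, fitted2, atol=1e-6)

    def test_variance_function_standardizes_residuals(self):
        tab = synth.simulate_long_table(
            n_specimens=150, sigma_site=0.2, delta=-0.12, seed=11
        )
        fit = fit_gamm(
            tab, variance=VarianceStructure("exponential", "temperature")
        )
        df = tab.data
        X = fit.design.build(df)
        resid = df.shape_var.to_numpy() - X @ fit.beta
        sd = fit.residual_sd(df.temperature.to_numpy(), df.pc.to_numpy())
        z = resid / sd
        slope, _, _, p, se = stats.linregress(df.temperature, np.abs(z))
        assert abs(slope) < 3 * se + 0.01

    def test_constant_variance_covariate_rejected(self):
        tab = synth.simulate_long_table(n_specimens=30, seed=12)
        data = tab.data.copy()
        data["chla"] = 5.0
        with pytest.raises(GammError, match="constant"):
            fit_gamm(
                LongShapeTable(data),
                FormulaSpec(smooth_terms=("temperature", "salinity")),
                variance=VarianceStructure("exponential", "chla"),
            )


class TestComparison:
    def test_identical_models_zero_delta(self):
        tab = synth.simulate_long_table(n_specimens=40, sigma_site=0.2, seed=13)
        f1 = fit_gamm(tab, method="REML")
        f2 = fit_gamm(tab, method="REML")
        comp = compare_models({"a": f1, "b": f2})
        assert comp.loc["a", "AICc"] == pytest.approx(comp.loc["b", "AICc"], abs=1e-6)
        assert comp["dAICc"].max() == pytest.approx(0.0, abs=1e-6)

    def test_lrt_df_and_method_guards(self):
        tab = synth.simulate_long_table(n_specimens=40, sigma_site=0.2, seed=14)
        ident = fit_gamm(tab, variance=VarianceStructure("identity"), method="REML")
        expo = fit_gamm(
            tab, variance=VarianceStructure("exponential", "temperature"),
            method="REML",
        )
        comp = compare_models(
            {"identity": ident, "exp": expo}, [("identity", "exp")]
        )
        assert comp.loc["exp", "lrt_df"] == 5
        assert comp.loc["exp", "lrt_stat"] >= -1e-8
        ml = fit_gamm(tab, method="ML")
        with pytest.raises(GammError, match="methods"):
            compare_models({"a": ident, "b": ml}, [("a", "b")])

    def test_aicc_approaches_aic_for_large_n(self):
        tab = synth.simulate_long_table(n_specimens=2000, k_pcs=2, seed=15)
        fit = fit_gamm(
            tab, FormulaSpec(smooth_terms=(), linear_terms=("length",)), method="ML"
        )
        assert (fit.aicc - fit.aic) / abs(fit.aic) < 1e-3


class TestPrediction:
    def test_prediction_at_means_equals_intercept(self):
        tab = synth.simulate_long_table(
            n_specimens=60, length_slopes={"PC2": 0.4}, sigma_site=0.2, seed=16
        )
        fit = fit_gamm(tab, method="REML")
        grid = pd.DataFrame({"length": [tab.data.length.mean()]})
        out = predict_with_ci(fit, grid, "PC2")
        i = fit.design.column_names.index("PC2")
        assert out.fit.iloc[0] == pytest.approx(fit.beta[i], abs=1e-8)
        assert not out.extrapolated.iloc[0]

    def test_extrapolation_flagged_and_unknown_pc_rejected(self):
        tab = synth.simulate_long_table(n_specimens=40, sigma_site=0.2, seed=17)
        fit = fit_gamm(tab, method="REML")
        out = predict_with_ci(fit, pd.DataFrame({"length": [500.0]}), "PC1")
        assert out.extrapolated.iloc[0]
        with pytest.raises(GammError, match="unknown pc_label"):
            predict_with_ci(fit, pd.DataFrame({"length": [50.0]}), "PC9")

    def test_monotone_effect_recovered_in_curve(self):
        tab = synth.simulate_long_table(
            n_specimens=250, salinity_slopes={"PC1": 0.08}, sigma_site=0.1, seed=18
        )
        fit = fit_gamm(tab, method="REML")
        lo, hi = tab.data.salinity.quantile([0.05, 0.95])
        grid = pd.DataFrame({"salinity": np.linspace(lo, hi, 25)})
        out = predict_with_ci(fit, grid, "PC1")
        assert (np.diff(out.fit) > 0).mean() > 0.9


class TestEffectSizes:
    def test_linear_truth_rescaled_correctly(self):
        beta = 0.06
        tab = synth.simulate_long_table(
            n_specimens=300, salinity_slopes={"PC3": beta}, sigma_site=0.2, seed=19
        )
        fit = fit_gamm(tab, method="REML")
        eff = effect_sizes(fit, tab)
        row = eff.query("covariate == 'salinity' and pc == 'PC3'").iloc[0]
        expected = beta * tab.data.salinity.std(ddof=1)
        assert row.ci_lower < expected < row.ci_upper
        assert row.significant

    def test_derivative_method_close_to_refit_for_linear_truth(self):
        # low noise so the fitted smooth stays close to the linear truth
        tab = synth.simulate_long_table(
            n_specimens=400, chla_slopes={"PC1": 0.3}, sigma_site=0.05,
            sigma=0.2, seed=20,
        )
        fit = fit_gamm(tab, method="REML")
        a = effect_sizes(fit, tab, method="linear_refit")
        b = effect_sizes(fit, tab, method="derivative")
        ra = a.query("covariate == 'chla' and pc == 'PC1'").iloc[0].estimate
        rb = b.query("covariate == 'chla' and pc == 'PC1'").iloc[0].estimate
        assert ra == pytest.approx(rb, rel=0.2)
        assert ra == pytest.approx(0.3 * tab.data.chla.std(ddof=1), rel=0.2)

    def test_null_covariate_ci_straddles_zero_mostly(self):
        hits = 0
        reps = 20
        for r in range(reps):
            tab = synth.simulate_long_table(
                n_specimens=60, sigma_site=0.2, seed=600 + r
            )
            fit = fit_gamm(tab, method="REML")
            eff = effect_sizes(fit, tab)
            row = eff.query("covariate == 'chla' and pc == 'PC1'").iloc[0]
            hits += row.ci_lower <= 0 <= row.ci_upper
        assert hits >= reps * 0.75
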