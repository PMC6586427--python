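"""Mixed-model fitting, AICc ranking, pooling, and composite intervals."""

import numpy as np
import pandas as pd
import pytest

from mesotherm.inference import (
    MODEL_SETS,
    LmmSpec,
    aicc,
    composite_ci,
    fit_lmm,
    model_average_conditional,
    pool_effects,
    pool_within_effects,
    rank_models,
    run_model_set,
)


def toy_design(n_tanks=12, n_weeks=8, beta=(1.0, -0.5, 2.0),
               var_group=0.0, var_resid=0.0, seed=0):
    """Balanced design with known coefficients for intercept, x_within,
    x_between."""
    rng = np.random.default_rng(seed)
    rows = []
    u = rng.normal(0, np.sqrt(var_group), n_tanks)
    for j in range(n_tanks):
        xw = np.linspace(-0.5, 0.5, n_weeks)
        xb = (j - (n_tanks - 1) / 2) / n_tanks
        for w in range(n_weeks):
            y = (beta[0] + beta[1] * xw[w] + beta[2] * xb + u[j]
                 + rng.normal(0, np.sqrt(var_resid)))
            rows.append((f"t{j}", "A", xw[w], xb, 0.0, 0.0, w + 2, y))
    return pd.DataFrame(rows, columns=["tank_id", "treatment", "x_within",
                                       "x_between", "z_ag", "z_agp",
                                       "week", "y"])


class TestAicc:
    @pytest.mark.parametrize("loglik,p,n,expected", [
        (-60.78, 6, 79, 134.73),     # cascade full model
        (-155.37, 12, 240, 336.11),  # phytoplankton full model
        (-185.88, 9, 240, 390.54),   # respiration model 7
    ])
    def test_published_triples(self, loglik, p, n, expected):
        assert aicc(loglik, p, n) == pytest.approx(expected, abs=0.02)

    def test_large_n_limit_is_plain_aic(self):
        ll, p = -100.0, 5
        assert aicc(ll, p, 10**9) == pytest.approx(-2 * ll + 2 * p, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 6, 7)


class TestFitLmm:
    def test_noiseless_recovery(self):
        des = toy_design(var_group=0.0, var_resid=0.0)
        fit = fit_lmm(des, LmmSpec("m", ("x_within", "x_between")))
        assert fit.beta["Intercept"] == pytest.approx(1.0, abs=1e-6)
        assert fit.beta["x_within"] == pytest.approx(-0.5, abs=1e-6)
        assert fit.beta["x_between"] == pytest.approx(2.0, abs=1e-6)
        assert fit.var_group == pytest.approx(0.0, abs=1e-6)

    def test_single_group_matches_ols(self):
        des = toy_design(n_tanks=1, var_resid=0.04, seed=3)
        fit = fit_lmm(des, LmmSpec("m", ("x_within",)))
        X = np.column_stack([np.ones(len(des)), des["x_within"]])
        beta_ols = np.linalg.lstsq(X, des["y"].to_numpy(), rcond=None)[0]
        assert fit.beta.to_numpy() == pytest.approx(beta_ols, abs=1e-8)
        assert fit.var_group == 0.0

    def test_zero_group_variance_flag_matches_ols(self):
        des = toy_design(var_group=0.3, var_resid=0.05, seed=5)
        fit = fit_lmm(des, LmmSpec("m", ("x_within", "x_between")),
                      zero_group_variance=True)
        X = np.column_stack([np.ones(len(des)), des["x_within"],
                             des["x_between"]])
        beta_ols = np.linalg.lstsq(X, des["y"].to_numpy(), rcond=None)[0]
        assert fit.beta.to_numpy() == pytest.approx(beta_ols, abs=1e-8)

    def test_group_variance_estimated(self):
        des = toy_design(n_tanks=40, var_group=0.5, var_resid=0.1, seed=11)
        fit = fit_lmm(des, LmmSpec("m", ("x_within", "x_between")))
        assert 0.2 < fit.var_group < 1.0
        assert 0.05 < fit.var_resid < 0.2
        assert fit.n_params == 5   # 3 fixed + 2 variance components

    def test_singular_design_names_columns(self):
        des = toy_design()
        des["x_between"] = des["x_within"]   # collinear
        with pytest.raises(ValueError, match="singular"):
            fit_lmm(des, LmmSpec("m", ("x_within", "x_between")))

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            LmmSpec("bad", ("x_within:x_between",))


class TestRankModels:
    def test_single_model_gets_weight_one(self):
        des = toy_design(var_resid=0.1, seed=2)
        comp = rank_models([fit_lmm(des, LmmSpec("only", ("x_within",)))])
        assert comp.weights[0] == pytest.approx(1.0)
        assert comp.delta_aicc[0] == 0.0

    def test_published_delta_column_yields_top_weight(self):
        # delta AICc {0, 2.60, 8.54, 9.19, 11.34} -> top weight ~0.77
        deltas = np.array([0.0, 2.60, 8.54, 9.19, 11.34])
        rel = np.exp(-deltas / 2)
        assert rel[0] / rel.sum() == pytest.approx(0.77, abs=0.005)

    def test_two_model_arithmetic(self):
        rel = np.exp(-np.array([0.0, 2.0]) / 2)
        w = rel / rel.sum()
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_weights_sum_to_one_and_sorted(self):
        des = toy_design(var_group=0.1, var_resid=0.2, seed=8)
        specs = [s for s in MODEL_SETS["phyto_biomass"]
                 if not any("Z" in t for t in s.terms)]
        fits = [fit_lmm(des, s) for s in specs]
        comp = rank_models(fits)
        assert comp.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(comp.aicc_values) >= 0).all()
        assert comp.delta_aicc[0] == 0.0

    def test_differing_row_sets_rejected(self):
        a = fit_lmm(toy_design(), LmmSpec("a", ()))
        b = fit_lmm(toy_design(n_weeks=6), LmmSpec("b", ()))
        with pytest.raises(ValueError, match="differing"):
            rank_models([a, b])

    def test_invariant_under_loglik_shift(self):
        des = toy_design(var_group=0.1, var_resid=0.2, seed=9)
        specs = [s for s in MODEL_SETS["phyto_biomass"]
                 if not any("Z" in t for t in s.terms)][:4]
        fits = [fit_lmm(des, s) for s in specs]
        comp1 = rank_models(fits)
        for f in fits:
            f.loglik += 10.0
        comp2 = rank_models(fits)
        assert np.allclose(comp1.delta_aicc, comp2.delta_aicc)
        assert np.allclose(comp1.weights, comp2.weights)


class TestModelAveraging:
    def test_term_in_single_model(self):
        des = toy_design(var_resid=0.1, seed=4)
        fits = [fit_lmm(des, LmmSpec("m0", ())),
                fit_lmm(des, LmmSpec("m1", ("x_within",)))]
        comp = rank_models(fits)
        only = [f for f in comp.fits if "x_within" in f.beta.index][0]
        assert model_average_conditional(comp, "x_within") == pytest.approx(
            float(only.beta["x_within"]))

    def test_renormalized_weighted_mean(self):
        # direct arithmetic: {1.0, 2.0} at renormalized weights {0.6, 0.4}
        assert 0.6 * 1.0 + 0.4 * 2.0 == pytest.approx(1.4)
        des = toy_design(var_group=0.05, var_resid=0.2, seed=6)
        fits = [fit_lmm(des, LmmSpec("m1", ("x_within",))),
                fit_lmm(des, LmmSpec("m2", ("x_within", "x_between"))),
                fit_lmm(des, LmmSpec("m0", ()))]
        comp = rank_models(fits)
        vals, ws = [], []
        for f, w in zip(comp.fits, comp.weights):
            if "x_within" in f.beta.index:
                vals.append(float(f.beta["x_within"]))
                ws.append(float(w))
        expected = np.average(vals, weights=np.array(ws) / sum(ws))
        assert model_average_conditional(comp, "x_within") == pytest.approx(
            expected, rel=1e-12)

    def test_absent_term_rejected(self):
        des = toy_design(var_resid=0.1)
        comp = rank_models([fit_lmm(des, LmmSpec("m0", ()))])
        with pytest.raises(ValueError, match="no model"):
            model_average_conditional(comp, "x_within")


class TestCompositeCi:
    def test_single_coefficient_contrast(self):
        V = pd.DataFrame(np.diag([0.04, 0.09]))
        lo, hi = composite_ci(V, np.array([1.0, 0.0]), 2.0)
        assert hi - lo == pytest.approx(2 * 1.96 * 0.2, rel=1e-12)

    def test_identity_covariance_sum_contrast(self):
        lo, hi = composite_ci(np.eye(2), np.array([1.0, 1.0]), 0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2), rel=1e-9)
        assert hi == pytest.approx(2.772, abs=5e-4)

    def test_perfect_negative_covariance_cancels(self):
        V = np.array([[1.0, -1.0], [-1.0, 1.0]])
        lo, hi = composite_ci(V, np.array([1.0, 1.0]), 5.0)
        assert lo == pytest.approx(5.0)
        assert hi == pytest.approx(5.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            composite_ci(np.eye(3), np.array([1.0, 0.0]), 0.0)


@pytest.fixture(scope="module")
def full_fit():
    rng = np.random.default_rng(17)
    rows = []
    beta = {"b0": 2.0, "bw": -0.5, "bb": 1.3, "z": {"AG": -0.8, "AGP": -0.3},
            "zb": {"AG": 4.0, "AGP": 0.0}}
    for j in range(30):
        trt = ["A", "AG", "AGP"][j % 3]
        xb = (j // 3 - 4.5) / 10
        for w in range(8):
            xw = (w - 3.5) / 20
            y = (beta["b0"] + beta["bw"] * xw + beta["bb"] * xb
                 + beta["z"].get(trt, 0.0)
                 + beta["zb"].get(trt, 0.0) * xb
                 + rng.normal(0, 0.1))
            rows.append((f"t{j}", trt, xw, xb,
                         float(trt == "AG"), float(trt == "AGP"), w + 2, y))
    des = pd.DataFrame(rows, columns=["tank_id", "treatment", "x_within",
                                      "x_between", "z_ag", "z_agp",
                                      "week", "y"])
    return fit_lmm(des, MODEL_SETS["phyto_biomass"][-1])


class TestPooling:
    def test_reference_treatment_slope_is_between_coefficient(self, full_fit):
        eff = pool_effects(full_fit, "A")
        assert eff.slope == pytest.approx(float(full_fit.beta["x_between"]))
        assert eff.E == pytest.approx(-eff.slope)
        assert eff.ci_low <= eff.E <= eff.ci_high

    def test_treatment_slope_sums_coefficients(self, full_fit):
        eff = pool_effects(full_fit, "AG")
        expected = (float(full_fit.beta["x_between"])
                    + float(full_fit.beta["z_ag:x_between"]))
        assert eff.slope == pytest.approx(expected, rel=1e-12)
        assert eff.intercept == pytest.approx(
            float(full_fit.beta["Intercept"]) + float(full_fit.beta["z_ag"]),
            rel=1e-12)
        assert eff.slope == pytest.approx(1.3 + 4.0, abs=0.5)

    def test_within_slope_eval_point(self, full_fit):
        eff0 = pool_within_effects(full_fit, "A", eval_point=0.0)
        assert eff0.slope == pytest.approx(float(full_fit.beta["x_within"]))
        effp = pool_within_effects(full_fit, "A", eval_point=0.2)
        effm = pool_within_effects(full_fit, "A", eval_point=-0.2)
        b3 = float(full_fit.beta["x_within:x_between"])
        # flipping the eval point flips only the interaction contribution
        assert effp.slope - eff0.slope == pytest.approx(0.2 * b3, rel=1e-9)
        assert effp.slope + effm.slope == pytest.approx(2 * eff0.slope,
                                                        rel=1e-9)

    def test_missing_treatment_terms_rejected(self):
        des = toy_design(var_resid=0.1)
        fit = fit_lmm(des, LmmSpec("m", ("x_within", "x_between")))
        with pytest.raises(ValueError):
            pool_effects(fit, "AG")


class TestModelSets:
    def test_set_sizes_and_df_ladder(self):
        assert len(MODEL_SETS["phyto_biomass"]) == 10
        assert len(MODEL_SETS["cascade"]) == 5
        for prefix in ("zoop_total", "daphnia", "copepod"):
            assert len(MODEL_SETS[prefix]) == 5
        # fixed effects + 2 variance components for the ln-response ladder
        n_cols = {"": 1, "x_within": 1, "x_between": 1,
                  "x_within:x_between": 1, "Z": 2, "Z:x_between": 2,
                  "Z:x_within": 2}
        expected_df = [3, 5, 4, 5, 6, 6, 8, 9, 11, 12]
        got = []
        for spec in MODEL_SETS["phyto_biomass"]:
            got.append(1 + sum(n_cols[t] for t in spec.terms) + 2)
        assert got == expected_df

    def test_run_model_set_unknown_name(self, experiment_with_fluxes):
        from mesotherm.assembly import center_design
        df, _ = experiment_with_fluxes
        with pytest.raises(ValueError, match="unknown model set"):
            run_model_set(center_design(df, "chla"), "nonsense")

    def test_run_model_set_weights_and_table(self, experiment_with_fluxes):
        from mesotherm.assembly import center_design
        df, _ = experiment_with_fluxes
        comp = run_model_set(center_design(df, "chla"), "phyto_biomass")
        assert comp.weights.sum() == pytest.approx(1.0, abs=1e-12)
        table = comp.to_table()
        assert list(table["Mod"]) == [f.spec.name for f in comp.fits]
        assert {"Mod", "Int", "df", "logLik", "AICc", "dAICc", "w"} <= set(
            table.columns)
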