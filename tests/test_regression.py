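"""Least-squares fitting and the full diagnostic battery."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from chlamydoe.design import DesignTable
from chlamydoe.factors import EffectTerm, FactorSpec
from chlamydoe.regression import (
    RankDeficientError,
    ResponseSurfaceModel,
    aicc_from_sse,
    build_model_matrix,
)


def _cont(name, lo=0.0, hi=1.0):
    return FactorSpec(name, "continuous", "", lo, hi)


def _random_problem(seed, n=30, k=4):
    """A generic continuous-factor fitting problem with noise."""
    rng = np.random.default_rng(seed)
    factors = [_cont(f"f{i}") for i in range(3)]
    data = pd.DataFrame({f.name: rng.uniform(0, 1, n) for f in factors})
    terms = [
        EffectTerm("linear", ("f0",)),
        EffectTerm("linear", ("f1",)),
        EffectTerm("quadratic", ("f0",)),
        EffectTerm("interaction", ("f0", "f1")),
        EffectTerm("linear", ("f2",)),
    ][:k]
    beta = rng.normal(0, 2, k)
    X, _, _ = build_model_matrix(data, terms, factors)
    y = 1.0 + X @ beta + rng.normal(0, 0.5, n)
    return y, data, terms, factors


class TestEncoding:
    def test_centering_constants_are_fit_row_means(self, factors, design):
        data = design.factor_data()
        terms = [EffectTerm("quadratic", ("acetate",))]
        _, _, centers = build_model_matrix(data, terms, factors)
        assert math.isclose(centers["acetate"], data["acetate"].mean())
        # dropping rows changes the realized centering
        sub = data.iloc[:30]
        _, _, c2 = build_model_matrix(sub, terms, factors)
        assert math.isclose(c2["acetate"], sub["acetate"].mean())
        assert c2["acetate"] != centers["acetate"]

    def test_center_row_second_order_columns_vanish(self):
        factors = [_cont("a"), _cont("b")]
        # symmetric corners + center: factor means equal the midpoints
        data = pd.DataFrame({"a": [0, 0, 1, 1, 0.5], "b": [0, 1, 0, 1, 0.5]})
        terms = [EffectTerm("quadratic", ("a",)), EffectTerm("interaction", ("a", "b"))]
        X, _, _ = build_model_matrix(data, terms, factors)
        assert np.allclose(X[-1], 0.0)

    def test_ordinal_indicator_and_extension(self):
        factors = [_cont("x"), FactorSpec("z", "ordinal", "", levels=(0.035, 1.5))]
        data = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0], "z": [0.035, 0.035, 1.5, 1.5]})
        terms = [EffectTerm("linear", ("z",)), EffectTerm("interaction", ("x", "z"))]
        X, names, centers = build_model_matrix(data, terms, factors)
        assert list(X[:, 0]) == [0.0, 0.0, 1.0, 1.0]
        np.testing.assert_allclose(X[:, 1], [0, 0, -0.5, 0.5])  # ind * (x - 0.5)

    def test_quadratic_on_ordinal_rejected(self):
        factors = [FactorSpec("z", "ordinal", "", levels=(0.0, 1.0))]
        data = pd.DataFrame({"z": [0.0, 1.0]})
        with pytest.raises(ValueError, match="ordinal"):
            build_model_matrix(data, [EffectTerm("quadratic", ("z",))], factors)


class TestOLS:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_normal_equations_oracle(self, seed):
        """Coefficients equal inv(X'X) X'y computed by explicit inversion."""
        y, data, terms, factors = _random_problem(seed, k=min(4 + seed % 2, 5))
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        X, _, _ = build_model_matrix(data, terms, factors)
        X1 = np.column_stack([np.ones(len(y)), X])
        oracle = np.linalg.inv(X1.T @ X1) @ X1.T @ y
        np.testing.assert_allclose(res.params.to_numpy(), oracle, rtol=1e-8)

    def test_matches_statsmodels(self):
        y, data, terms, factors = _random_problem(7)
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        X, _, _ = build_model_matrix(data, terms, factors)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, rtol=1e-10)
        assert math.isclose(res.rsquared, ref.rsquared, rel_tol=1e-10)
        assert math.isclose(res.fvalue, ref.fvalue, rel_tol=1e-10)
        assert math.isclose(res.f_pvalue, ref.f_pvalue, rel_tol=1e-8)

    def test_exact_linear_response(self):
        factors = [_cont("x")]
        data = pd.DataFrame({"x": np.linspace(0, 1, 10)})
        y = 2.0 + 3.0 * data["x"].to_numpy()
        res = ResponseSurfaceModel(y, data, [EffectTerm("linear", ("x",))], factors).fit()
        assert math.isclose(res.rsquared, 1.0, abs_tol=1e-12)
        np.testing.assert_allclose(res.resid, 0.0, atol=1e-10)
        assert res.rmse == pytest.approx(0.0, abs=1e-10)
        assert res.mae == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only(self):
        factors = [_cont("x")]
        data = pd.DataFrame({"x": [0.1, 0.2, 0.3, 0.9]})
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = ResponseSurfaceModel(y, data, [], factors).fit()
        assert math.isclose(res.params["intercept"], y.mean())
        assert res.ss_model == pytest.approx(0.0, abs=1e-10)

    def test_rank_deficiency_names_aliased_columns(self):
        factors = [_cont("a"), _cont("b")]
        data = pd.DataFrame({"a": [0.1, 0.4, 0.7, 0.9, 0.2],
                             "b": [0.1, 0.4, 0.7, 0.9, 0.2]})  # perfect alias
        terms = [EffectTerm("linear", ("a",)), EffectTerm("linear", ("b",)),
                 EffectTerm("quadratic", ("a",))]
        y = np.arange(5.0)
        with pytest.raises(RankDeficientError) as err:
            ResponseSurfaceModel(y, data, terms, factors).fit()
        assert any(name in err.value.aliased for name in ("a", "b"))


class TestDecompositionInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_ss_and_df_identities(self, seed):
        y, data, terms, factors = _random_problem(seed)
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        assert math.isclose(res.ss_total, res.ss_model + res.ss_error, rel_tol=1e-8)
        assert res.df_total == res.df_model + res.df_error
        assert 0.0 <= res.rsquared <= 1.0
        assert res.rsquared_adj <= res.rsquared
        assert res.mae <= res.rmse + 1e-12
        assert 0.0 <= res.f_pvalue <= 1.0

    def test_error_ss_splits_into_pure_and_lof(self, design, models):
        from chlamydoe.simulate import NoiseModel, generate_responses
        resp = generate_responses(design, {"CR": models["CR"]},
                                  NoiseModel(seed=3, missing_runs={}))
        res = ResponseSurfaceModel.from_tables(design, resp, "CR",
                                               models["CR"].terms()).fit()
        lof = res.lack_of_fit
        assert lof.available
        assert math.isclose(res.ss_error, lof.ss_pure + lof.ss_lof, rel_tol=1e-8)
        assert res.df_error == lof.df_pure + lof.df_lof
        assert 0.0 <= lof.pvalue <= 1.0

    def test_parameterization_invariance(self):
        """Different centering constants, identical fit and SS split."""
        y, data, terms, factors = _random_problem(11)
        res_a = ResponseSurfaceModel(y, data, terms, factors).fit()
        shifted = {"f0": 0.1, "f1": 0.9, "f2": 0.3}
        res_b = ResponseSurfaceModel(y, data, terms, factors, centers=shifted).fit()
        np.testing.assert_allclose(res_a.fittedvalues, res_b.fittedvalues, rtol=1e-8)
        assert math.isclose(res_a.ss_model, res_b.ss_model, rel_tol=1e-8)
        assert math.isclose(res_a.ss_error, res_b.ss_error, rel_tol=1e-8)


class TestAnova:
    def test_whole_model_f_from_r2(self):
        y, data, terms, factors = _random_problem(3)
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        n, k = res.nobs, res.k_effects
        f = (res.rsquared / k) / ((1 - res.rsquared) / (n - k - 1))
        assert math.isclose(res.fvalue, f, rel_tol=1e-10)

    def test_single_term_effect_p_equals_whole_model_p(self):
        y, data, _, factors = _random_problem(5)
        terms = [EffectTerm("linear", ("f0",))]
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        assert math.isclose(res.effect_pvalues["f0"], res.f_pvalue, rel_tol=1e-10)

    def test_orthogonal_columns_effect_ss_sums_to_model_ss(self):
        # 2^2 factorial replicated: linear columns are exactly orthogonal
        factors = [_cont("a", -1, 1), _cont("b", -1, 1)]
        corners = [(-1, -1), (-1, 1), (1, -1), (1, 1)] * 4
        data = pd.DataFrame(corners, columns=["a", "b"])
        rng = np.random.default_rng(0)
        y = 1 + 2 * data["a"] - 1.5 * data["b"] + rng.normal(0, 0.3, len(data))
        terms = [EffectTerm("linear", ("a",)), EffectTerm("linear", ("b",))]
        res = ResponseSurfaceModel(y.to_numpy(), data, terms, factors).fit()
        assert math.isclose(res.effect_ss.sum(), res.ss_model, rel_tol=1e-8)


class TestLackOfFit:
    def test_unavailable_without_replicates(self):
        y, data, terms, factors = _random_problem(0)  # all rows distinct
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        assert not res.lack_of_fit.available

    def test_saturated_model_zero_lof(self):
        # one parameter per replicate group: lack-of-fit SS collapses
        factors = [_cont("x")]
        data = pd.DataFrame({"x": [0.0, 0.0, 0.5, 0.5, 1.0, 1.0, 1.0]})
        rng = np.random.default_rng(1)
        y = 1 + 2 * data["x"].to_numpy() + rng.normal(0, 0.2, 7)
        terms = [EffectTerm("linear", ("x",)), EffectTerm("quadratic", ("x",))]
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        lof = res.lack_of_fit
        assert lof.ss_lof == pytest.approx(0.0, abs=1e-9)
        assert not lof.available  # df_lof = 3 groups - 1 - 2 effects = 0


class TestBetaWeights:
    def test_univariate_beta_is_pearson_r(self):
        rng = np.random.default_rng(2)
        factors = [_cont("x")]
        data = pd.DataFrame({"x": rng.uniform(0, 1, 25)})
        y = 0.3 + 1.7 * data["x"].to_numpy() + rng.normal(0, 0.4, 25)
        res = ResponseSurfaceModel(y, data, [EffectTerm("linear", ("x",))], factors).fit()
        r = np.corrcoef(data["x"], y)[0, 1]
        assert math.isclose(res.beta_weights["x"], r, rel_tol=1e-10)

    def test_invariant_under_factor_rescaling(self):
        y, data, terms, factors = _random_problem(9)
        res_a = ResponseSurfaceModel(y, data, terms, factors).fit()
        scaled = data.copy()
        scaled["f0"] = data["f0"] * 1000.0  # e.g. unit change g -> mg
        factors_b = [_cont("f0", 0, 1000), _cont("f1"), _cont("f2")]
        res_b = ResponseSurfaceModel(y, scaled, terms, factors_b).fit()
        np.testing.assert_allclose(
            res_a.beta_weights.to_numpy(), res_b.beta_weights.to_numpy(), rtol=1e-10
        )


class TestAICc:
    def test_hand_oracle_five_points(self):
        # n=5, one predictor: freeze the closed form evaluated by hand
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = np.array([1.0, 1.2, 1.9, 2.4, 3.1])
        factors = [_cont("x")]
        res = ResponseSurfaceModel(y, pd.DataFrame({"x": x}),
                                   [EffectTerm("linear", ("x",))], factors).fit()
        n, kp = 5, 3
        expected = (n * math.log(2 * math.pi * res.ss_error / n) + n
                    + 2 * kp + 2 * kp * (kp + 1) / (n - kp - 1))
        assert math.isclose(res.aicc, expected, rel_tol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_aicc_exceeds_aic(self, seed):
        y, data, terms, factors = _random_problem(seed)
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        n, kp = res.nobs, res.k_effects + 2
        aic = n * math.log(2 * math.pi * res.ss_error / n) + n + 2 * kp
        assert res.aicc > aic

    def test_noise_column_raises_median_aicc(self):
        """Adding a true-zero effect worsens the criterion on average."""
        rng = np.random.default_rng(0)
        deltas = []
        factors = [_cont("x"), _cont("z")]
        for _ in range(200):
            data = pd.DataFrame({"x": rng.uniform(0, 1, 25),
                                 "z": rng.uniform(0, 1, 25)})
            y = 1 + 2 * data["x"].to_numpy() + rng.normal(0, 0.5, 25)
            small = ResponseSurfaceModel(y, data, [EffectTerm("linear", ("x",))], factors).fit()
            big = ResponseSurfaceModel(y, data, [EffectTerm("linear", ("x",)),
                                                 EffectTerm("linear", ("z",))], factors).fit()
            deltas.append(big.aicc - small.aicc)
        assert np.median(deltas) > 0

    def test_degenerate_penalty_returns_inf(self):
        with pytest.warns(UserWarning):
            assert aicc_from_sse(1.0, 4, 1) == math.inf


class TestMetricsAndReporting:
    def test_rmse_percent_of_average_scale(self):
        y, data, terms, factors = _random_problem(13)
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        scale = y.mean() - y.min()
        assert math.isclose(res.average_scale, scale)
        assert math.isclose(res.rmse_pct_scale, 100 * res.rmse / scale)

    def test_equation_renders_centered_form(self, design, models):
        from chlamydoe.simulate import NoiseModel, generate_responses
        resp = generate_responses(design, {"MA_ALT": models["MA_ALT"]},
                                  NoiseModel(sigma={}, missing_runs={}))
        m = models["MA_ALT"]
        res = ResponseSurfaceModel(
            resp["MA_ALT"].to_numpy(), design.factor_data(), m.terms(),
            design.factors, response="MA_ALT", centers=m.centers()).fit()
        eq = res.equation()
        assert eq.startswith("MA_ALT = 11.1")
        assert "(acetate-0.488)^2" in eq

    def test_summary_orders_effects_by_p(self):
        y, data, terms, factors = _random_problem(4)
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        text = res.summary()
        order = res.effect_pvalues.sort_values().index
        positions = [text.index(f"\n{name} ") if f"\n{name} " in text else text.index(name)
                     for name in order]
        assert positions == sorted(positions)

    def test_predict_on_new_rows_uses_stored_centers(self):
        y, data, terms, factors = _random_problem(6)
        res = ResponseSurfaceModel(y, data, terms, factors).fit()
        np.testing.assert_allclose(res.predict(data), res.fittedvalues, rtol=1e-10)
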