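"""Logistic fits, likelihood-ratio test, stratum ORs, RERI and its intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from heatpm.simulate import TrueModel, simulate_analytic_table
from heatpm.stats import (
    DesignSpec,
    LogisticFit,
    additive_result,
    build_design,
    fit_logistic,
    lrt_interaction,
    reri_ci_delta,
    reri_ci_profile,
    reri_from_fit,
    reri_point,
    run_analysis,
    stratum_ors,
)

SPEC = DesignSpec("case", "full", "EHE95")


@pytest.fixture(scope="module")
def interaction_data(interaction_model):
    return simulate_analytic_table(1500, 1500, interaction_model, seed=101)


class TestBuildDesign:
    def test_joint_coding_patterns(self, interaction_data):
        X, y, _ = build_design(interaction_data, SPEC, "joint_4level")
        pm = interaction_data["pm_high"].to_numpy()
        ehe = interaction_data["ehe95_exposed"].to_numpy()
        both = pm & ehe
        row = X.loc[interaction_data.index[both][0]]
        assert (row["j_10"], row["j_01"], row["j_11"]) == (0.0, 0.0, 1.0)
        ref = X.loc[interaction_data.index[~pm & ~ehe][0]]
        assert (ref["j_10"], ref["j_01"], ref["j_11"]) == (0.0, 0.0, 0.0)

    def test_product_column_is_elementwise_product(self, interaction_data):
        X, _, _ = build_design(interaction_data, SPEC, "product_term")
        np.testing.assert_array_equal(X["pm_x_ehe"], X["pm_high"] * X["ehe"])

    def test_full_population_gets_season_indicator(self, interaction_data):
        X, _, _ = build_design(interaction_data, SPEC, "product_term")
        assert "spring_summer" in X.columns
        X2, _, _ = build_design(
            interaction_data, DesignSpec("case", "any_summer", "EHE95"), "product_term")
        assert "spring_summer" not in X2.columns

    def test_population_filters_nest(self, interaction_data):
        sizes = {}
        for filt in ("full", "any_spring_summer", "entire_spring_summer"):
            _, y, info = build_design(
                interaction_data, DesignSpec("case", filt, "EHE95"), "product_term")
            sizes[filt] = info["n_used"]
        assert sizes["entire_spring_summer"] <= sizes["any_spring_summer"] <= sizes["full"]

    def test_complete_case_drops_missing(self, interaction_data):
        df = interaction_data.copy()
        df.loc[df.index[:10], "mean_dew_point"] = np.nan
        _, _, info = build_design(df, SPEC, "product_term")
        assert info["n_dropped"] == 10

    def test_unknown_coding_rejected(self, interaction_data):
        with pytest.raises(ValueError):
            build_design(interaction_data, SPEC, "nonsense")


class TestFitLogistic:
    @pytest.mark.parametrize("n_cases, n_controls, expected", [
        (50, 50, 0.0),
        (20, 80, np.log(0.25)),
    ])
    def test_intercept_only_closed_form(self, n_cases, n_controls, expected):
        y = np.r_[np.ones(n_cases), np.zeros(n_controls)]
        X = pd.DataFrame({"const": np.ones(n_cases + n_controls)})
        fit = fit_logistic(X, y)
        assert fit.converged
        assert fit.params["const"] == pytest.approx(expected, abs=1e-6)

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"const": [1.0, 1.0]}), np.array([1.0, 1.0]))

    def test_separation_flagged_not_silent(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        X = pd.DataFrame({"const": 1.0, "x": y.copy()})  # perfect separation
        fit = fit_logistic(X, y)
        assert not fit.converged

    def test_recovers_known_coefficients(self, interaction_model):
        df = simulate_analytic_table(20_000, 20_000, interaction_model, seed=55)
        X, y, _ = build_design(df, SPEC, "product_term")
        fit = fit_logistic(X, y)
        for name, truth in [("pm_high", interaction_model.beta_pm),
                            ("ehe", interaction_model.beta_ehe),
                            ("pm_x_ehe", interaction_model.beta_interaction)]:
            se = np.sqrt(fit.cov.loc[name, name])
            assert abs(fit.params[name] - truth) < 3 * se

    def test_covariance_symmetric_psd(self, interaction_data):
        X, y, _ = build_design(interaction_data, SPEC, "product_term")
        fit = fit_logistic(X, y)
        V = fit.cov.to_numpy()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > -1e-10)


class TestLRT:
    def test_identical_likelihoods(self):
        a = LogisticFit(pd.Series(dtype=float), pd.DataFrame(), -100.0, True, 10)
        b = LogisticFit(pd.Series(dtype=float), pd.DataFrame(), -100.0, True, 10)
        stat, p = lrt_interaction(a, b)
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("stat, expected_p", [(2.706, 0.100), (3.841, 0.050)])
    def test_chi_square_1df_tail(self, stat, expected_p):
        full = LogisticFit(pd.Series(dtype=float), pd.DataFrame(), -100.0 + stat / 2, True, 10)
        red = LogisticFit(pd.Series(dtype=float), pd.DataFrame(), -100.0, True, 10)
        _, p = lrt_interaction(full, red)
        assert p == pytest.approx(expected_p, abs=1e-3)

    def test_negative_statistic_rejected(self):
        full = LogisticFit(pd.Series(dtype=float), pd.DataFrame(), -101.0, True, 10)
        red = LogisticFit(pd.Series(dtype=float), pd.DataFrame(), -100.0, True, 10)
        with pytest.raises(ValueError):
            lrt_interaction(full, red)


class TestStratumORs:
    def _fit_pair(self, df):
        X, y, _ = build_design(df, SPEC, "product_term")
        full = fit_logistic(X, y)
        red = fit_logistic(X.drop(columns="pm_x_ehe"), y)
        return X, y, full, red

    def test_null_betas_give_unit_ors(self):
        idx = ["const", "pm_high", "ehe", "pm_x_ehe"]
        fit = LogisticFit(pd.Series(0.0, index=idx),
                          pd.DataFrame(np.eye(4) * 0.01, index=idx, columns=idx),
                          -10.0, True, 100)
        m = stratum_ors(fit, (0.0, 1.0))
        assert m.or_pm_no_ehe == pytest.approx(1.0)
        assert m.or_pm_ehe == pytest.approx(1.0)

    def test_refuses_nonconverged_fit(self):
        fit = LogisticFit(pd.Series(dtype=float), pd.DataFrame(), np.nan, False, 0)
        with pytest.raises(ValueError):
            stratum_ors(fit, (0.0, 1.0))

    def test_reference_swap_equivalence(self, interaction_data):
        """OR(PM | EHE) and its CI from the covariance sum must match a refit
        with the heat-event stratum recoded (1 - EHE)."""
        X, y, full, red = self._fit_pair(interaction_data)
        m = stratum_ors(full, lrt_interaction(full, red))
        Xs = X.copy()
        Xs["ehe"] = 1.0 - Xs["ehe"]
        Xs["pm_x_ehe"] = Xs["pm_high"] * Xs["ehe"]
        swapped = fit_logistic(Xs, y)
        b = float(swapped.params["pm_high"])
        se = float(np.sqrt(swapped.cov.loc["pm_high", "pm_high"]))
        assert m.or_pm_ehe == pytest.approx(np.exp(b), rel=1e-5)
        assert m.ci_pm_ehe[0] == pytest.approx(np.exp(b - 1.959963984540054 * se), rel=1e-4)
        assert m.ci_pm_ehe[1] == pytest.approx(np.exp(b + 1.959963984540054 * se), rel=1e-4)

    def test_modification_flag_uses_alpha_0_1(self, interaction_data):
        X, y, full, red = self._fit_pair(interaction_data)
        lrt = lrt_interaction(full, red)
        m = stratum_ors(full, lrt)
        assert m.modification_flag == (m.lrt_p < 0.1)


class TestRERI:
    @pytest.mark.parametrize("ors, expected", [
        ((1.0, 1.0, 1.0), 0.0),
        ((2.0, 1.5, 1.2), 0.3),
        ((1.7, 1.4, 1.3), 0.0),  # OR11 = OR10 + OR01 - 1: exact additivity
    ])
    def test_point_formula(self, ors, expected):
        or11, or10, or01 = ors
        assert reri_point(or11, or10, or01) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            reri_point(1.0, 0.0, 1.0)

    def test_point_invariant_to_exposure_relabeling(self):
        assert reri_point(2.2, 1.5, 1.2) == reri_point(2.2, 1.2, 1.5)

    def test_delta_interval_degenerate_and_contains_point(self):
        idx = ["const", "j_10", "j_01", "j_11"]
        params = pd.Series([0.0, np.log(1.5), np.log(1.2), np.log(2.2)], index=idx)
        zero_cov = pd.DataFrame(np.zeros((4, 4)), index=idx, columns=idx)
        fit = LogisticFit(params, zero_cov, -10.0, True, 100)
        lo, hi = reri_ci_delta(fit)
        assert lo == pytest.approx(0.5, abs=1e-12)
        assert hi == pytest.approx(0.5, abs=1e-12)

    def test_profile_interval_defining_property(self, interaction_model):
        """Endpoints must sit exactly where the profile deviance equals the
        chi-square(1) 95% critical value, and bracket the point estimate."""
        df = simulate_analytic_table(1500, 1500, interaction_model, seed=77)
        X, y, _ = build_design(df, SPEC, "joint_4level")
        fit = fit_logistic(X, y)
        reri_hat = reri_from_fit(fit)
        lo, hi = reri_ci_profile(X, y, fit=fit)
        assert lo < reri_hat < hi
        crit = chi2.ppf(0.95, 1)
        for endpoint in (lo, hi):
            dev = _profile_deviance(X, y, fit, endpoint)
            assert dev == pytest.approx(crit, abs=1e-3)

    def test_profile_and_delta_agree_asymptotically(self, interaction_model):
        df = simulate_analytic_table(25_000, 25_000, interaction_model, seed=78)
        X, y, _ = build_design(df, SPEC, "joint_4level")
        fit = fit_logistic(X, y)
        d_lo, d_hi = reri_ci_delta(fit)
        p_lo, p_hi = reri_ci_profile(X, y, fit=fit)
        assert abs((p_hi - p_lo) - (d_hi - d_lo)) / (d_hi - d_lo) < 0.10


def _profile_deviance(X, y, fit, r):
    """Independent evaluation of the profile deviance at a fixed RERI value,
    maximizing the constrained likelihood from scratch with a generic
    optimizer (no analytic gradient)."""
    from scipy.optimize import minimize
    from scipy.special import expit

    cols = list(X.columns)
    Xv = np.asarray(X, float)
    yv = np.asarray(y, float)
    j10, j01, j11 = (cols.index(k) for k in ("j_10", "j_01", "j_11"))
    free = [i for i in range(len(cols)) if i != j11]

    def nll(theta):
        beta = np.zeros(len(cols))
        beta[free] = theta
        s = np.exp(beta[j10]) + np.exp(beta[j01]) + r - 1.0
        if s <= 0:
            return 1e10
        beta[j11] = np.log(s)
        eta = Xv @ beta
        return -(yv @ eta - np.logaddexp(0.0, eta).sum())

    res = minimize(nll, fit.params.to_numpy()[free], method="Nelder-Mead",
                   options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
    return 2.0 * (fit.llf + res.fun)


class TestAdditiveResultAndRunAnalysis:
    def test_reri_identity_within_fit(self, interaction_model):
        df = simulate_analytic_table(800, 800, interaction_model, seed=91)
        X, y, info = build_design(df, SPEC, "joint_4level")
        a = additive_result(X, y, info, profile=False)
        assert a.reri == pytest.approx(a.or11 - a.or10 - a.or01 + 1.0, abs=1e-12)

    def test_cell_cardinality_nesting_and_determinism(self, interaction_model):
        df = simulate_analytic_table(600, 600, interaction_model, seed=92)
        df2 = df.copy()
        df2["outcome_group"] = df2["outcome_group"].replace("case", "caseB")
        both = pd.concat([df, df2], ignore_index=True)
        res = run_analysis(both, outcome_groups=("case", "caseB"), profile_ci=False)
        assert len(res) == 2 * 4 * 2
        ok = res[res["status"] == "ok"]
        for outcome in ("case", "caseB"):
            sub = ok[ok["outcome_group"] == outcome].set_index("population_filter")
            if {"full", "any_spring_summer", "entire_spring_summer"} <= set(sub.index):
                n = sub["n_used"].groupby(level=0).first()
                assert n["entire_spring_summer"] <= n["any_spring_summer"] <= n["full"]
        res2 = run_analysis(both, outcome_groups=("case", "caseB"), profile_ci=False)
        pd.testing.assert_frame_equal(res, res2)
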