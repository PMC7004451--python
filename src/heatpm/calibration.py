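"""Simulation studies: test-size calibration, CI coverage, parameter recovery.

These drivers tie the generator to the estimators: they simulate replicate
case-control datasets under a known logistic truth, run the interaction
machinery on each, and summarize operating characteristics -- the empirical
type-I error of the multiplicative-interaction likelihood-ratio test, the
empirical coverage of the likelihood-based RERI interval, and large-cohort
recovery of the true stratum odds ratios and RERI.
"""

from __future__ import annotations

import numpy as np

from .simulate import DEFAULT_COVARIATE_BETAS, TrueModel, simulate_analytic_table
from .stats import (
    DesignSpec,
    ProfileCIError,
    additive_result,
    build_design,
    fit_logistic,
    lrt_interaction,
    reri_ci_profile,
    reri_from_fit,
    stratum_ors,
)

_SPEC = DesignSpec(outcome_group="case", population_filter="full", ehe_definition="EHE95")


def _child_seeds(seed, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2**31


def lrt_type1_error(n_reps: int = 1000, n_cases: int = 1500, n_controls: int = 1500,
                    alpha: float = 0.1, seed: int = 0,
                    or_pm: float = 1.5, or_ehe: float = 1.3,
                    intercept: float = -1.735) -> dict:
    """Empirical rejection rate of the product-term LRT under the
    multiplicative null (main effects only, no product term).

    Each replicate simulates a case-control dataset, fits the adjusted full
    and reduced models, and rejects when the LRT p-value is below ``alpha``.
    """
    model = TrueModel(intercept=intercept, beta_pm=np.log(or_pm),
                      beta_ehe=np.log(or_ehe), beta_interaction=0.0,
                      covariate_betas=dict(DEFAULT_COVARIATE_BETAS))
    rejections = 0
    n_done = 0
    for s in _child_seeds(seed, n_reps):
        df = simulate_analytic_table(n_cases, n_controls, model, seed=s)
        X, y, _ = build_design(df, _SPEC, "product_term")
        fit_full = fit_logistic(X, y)
        fit_red = fit_logistic(X.drop(columns="pm_x_ehe"), y)
        if not (fit_full.converged and fit_red.converged):
            continue
        _, p = lrt_interaction(fit_full, fit_red)
        rejections += p < alpha
        n_done += 1
    return {"rejection_rate": rejections / n_done, "n_reps": n_done,
            "rejections": rejections, "alpha": alpha}


def reri_coverage(n_reps: int = 500, n_cases: int = 2000, n_controls: int = 2000,
                  or10: float = 1.5, or01: float = 1.2, true_reri: float = 0.5,
                  level: float = 0.95, seed: int = 0,
                  intercept: float = -1.735) -> dict:
    """Empirical coverage of the profile-likelihood RERI interval.

    Replicates are generated from a joint-4-level truth with
    OR11 = true_reri - 1 + OR10 + OR01; each replicate's interval is checked
    for containing the true RERI.  Replicates where the fit or the profile
    search fails are excluded (and counted).
    """
    or11 = true_reri - 1.0 + or10 + or01
    model = TrueModel.from_joint_ors(intercept, or10, or01, or11,
                                     covariate_betas=DEFAULT_COVARIATE_BETAS)
    assert abs(model.true_reri() - true_reri) < 1e-12
    covered = 0
    n_done = 0
    n_failed = 0
    for s in _child_seeds(seed, n_reps):
        df = simulate_analytic_table(n_cases, n_controls, model, seed=s)
        X, y, _ = build_design(df, _SPEC, "joint_4level")
        try:
            fit = fit_logistic(X, y)
            lo, hi = reri_ci_profile(X, y, level=level, fit=fit)
        except (ProfileCIError, ValueError):
            n_failed += 1
            continue
        covered += lo <= true_reri <= hi
        n_done += 1
    return {"coverage": covered / n_done, "n_reps": n_done, "covered": covered,
            "n_failed": n_failed, "true_reri": true_reri, "level": level}


def parameter_recovery(n_cohort: int = 200_000, or_pm_no_ehe: float = 1.0,
                       or_pm_ehe: float = 1.6, or_ehe: float = 1.3,
                       intercept: float = -2.2, seed: int = 0) -> dict:
    """Fit the full generative cohort and compare estimates with the truth.

    The truth sets the PM odds ratio to ``or_pm_no_ehe`` without a heat event
    and ``or_pm_ehe`` with one (so the product-term coefficient is their
    log-ratio).  Returns fitted and true stratum ORs and RERI.
    """
    model = TrueModel(intercept=intercept, beta_pm=np.log(or_pm_no_ehe),
                      beta_ehe=np.log(or_ehe),
                      beta_interaction=np.log(or_pm_ehe / or_pm_no_ehe),
                      covariate_betas=dict(DEFAULT_COVARIATE_BETAS))
    df = _simulate_cohort(n_cohort, model, seed=_child_seeds(seed, 1)[0])

    X, y, _ = build_design(df, _SPEC, "product_term")
    fit_full = fit_logistic(X, y)
    fit_red = fit_logistic(X.drop(columns="pm_x_ehe"), y)
    m = stratum_ors(fit_full, lrt_interaction(fit_full, fit_red))

    Xj, yj, info = build_design(df, _SPEC, "joint_4level")
    fitj = fit_logistic(Xj, yj)
    a = additive_result(Xj, yj, info, profile=False)
    return {
        "or_pm_no_ehe": m.or_pm_no_ehe, "or_pm_ehe": m.or_pm_ehe,
        "true_or_pm_no_ehe": or_pm_no_ehe, "true_or_pm_ehe": or_pm_ehe,
        "reri": reri_from_fit(fitj), "true_reri": model.true_reri(),
        "reri_ci_delta": a.reri_ci_delta, "n": len(df),
    }


def _simulate_cohort(n: int, model: TrueModel, seed=None):
    """Full cohort at the analytic level (no case-control subsampling)."""
    import pandas as pd
    from scipy.special import expit

    from .simulate import DEFAULT_COVARIATE_PROBS, _draw_categorical, _linear_predictor

    rng = np.random.default_rng(seed)
    probs = DEFAULT_COVARIATE_PROBS
    df = pd.DataFrame({
        "pm_high": rng.random(n) < 0.2,
        "ehe95_exposed": rng.random(n) < 0.35,
        "maternal_age_cat": _draw_categorical(rng, probs["maternal_age_cat"], n),
        "education_cat": _draw_categorical(rng, probs["education_cat"], n),
        "race_ethnicity": _draw_categorical(rng, probs["race_ethnicity"], n),
        "mean_dew_point": rng.normal(12.0, 4.0, n),
    })
    u = rng.random(n)
    df["entire_window_spring_summer"] = u < 0.25
    df["any_day_spring_summer"] = u < 0.60
    df["any_day_summer"] = df["any_day_spring_summer"] & (rng.random(n) < 0.55)
    p = expit(_linear_predictor(df, model, "pm_high", "ehe95_exposed"))
    df["is_case"] = rng.random(n) < p
    df["outcome_group"] = np.where(df["is_case"], "case", "control")
    df["subject_id"] = [f"S{i:07d}" for i in range(1, n + 1)]
    return df
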