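"""Synthetic weather, monitor and case-control cohort generation.

Emulates the structure of a population-based case-control study of early
pregnancy environmental exposure: daily station temperature series with a
seasonal cycle and day-to-day (AR(1)) autocorrelation, so that multi-day
percentile-exceedance runs occur at realistic rates; log-normal daily PM2.5
monitor series with a seasonal cycle and missing days; pregnancies with
delivery dates spread across seasons; and case status drawn from a logistic
model with user-specified main-effect and interaction log-odds, then sampled
on outcome into a case-control table.

Everything is reproducible: a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .stats import covariate_dummies

DAYS_PER_YEAR = 365.25

#: marginal covariate distributions loosely matching a US birth cohort
DEFAULT_COVARIATE_PROBS = {
    "maternal_age_cat": {"<=19": 0.10, "20-34": 0.75, ">=35": 0.15},
    "education_cat": {"<12y": 0.20, ">=12y": 0.80},
    "race_ethnicity": {"NH-white": 0.55, "NH-black": 0.12, "Hispanic": 0.25, "other": 0.08},
}

#: mild covariate effects on the log-odds scale (keys = design-dummy names)
DEFAULT_COVARIATE_BETAS = {
    "age_le19": 0.10, "age_ge35": 0.15, "edu_lt12": 0.10,
    "race_nh_black": 0.05, "race_hispanic": 0.05, "race_other": 0.0,
    "dew_point": 0.01,
}


@dataclass
class TrueModel:
    """Generative logistic model for case status.

    Joint-category log-odds: b10 = beta_pm, b01 = beta_ehe,
    b11 = beta_pm + beta_ehe + beta_interaction.
    """

    intercept: float
    beta_pm: float = 0.0
    beta_ehe: float = 0.0
    beta_interaction: float = 0.0
    covariate_betas: dict = field(default_factory=dict)

    def joint_log_ors(self) -> tuple[float, float, float]:
        return (self.beta_pm, self.beta_ehe,
                self.beta_pm + self.beta_ehe + self.beta_interaction)

    def true_reri(self) -> float:
        b10, b01, b11 = self.joint_log_ors()
        return float(np.exp(b11) - np.exp(b10) - np.exp(b01) + 1.0)

    def true_stratum_ors(self) -> tuple[float, float]:
        """PM odds ratio (without EHE, with EHE)."""
        return float(np.exp(self.beta_pm)), float(np.exp(self.beta_pm + self.beta_interaction))

    @classmethod
    def from_joint_ors(cls, intercept: float, or10: float, or01: float, or11: float,
                       covariate_betas: dict | None = None) -> "TrueModel":
        if min(or10, or01, or11) <= 0:
            raise ValueError("odds ratios must be positive")
        return cls(
            intercept=intercept,
            beta_pm=float(np.log(or10)),
            beta_ehe=float(np.log(or01)),
            beta_interaction=float(np.log(or11 / (or10 * or01))),
            covariate_betas=dict(covariate_betas or {}),
        )


def _date_index(start_date, end_date) -> pd.DatetimeIndex:
    start, end = pd.Timestamp(start_date), pd.Timestamp(end_date)
    if start > end:
        raise ValueError("start_date must not be after end_date")
    return pd.date_range(start, end, freq="D")


def seasonal_mean(day_of_year, base: float, amplitude: float, peak_doy: float):
    """Single-sinusoid seasonal curve, maximized at ``peak_doy``."""
    doy = np.asarray(day_of_year, dtype=float)
    return base + amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / DAYS_PER_YEAR)


def _ar1(rng, n: int, rho: float, innovation_sd: float) -> np.ndarray:
    if innovation_sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter
    a0 = rng.normal(0.0, innovation_sd / np.sqrt(1.0 - rho**2))
    innov = rng.normal(0.0, innovation_sd, size=n)
    # stationary start: filter with the initial state carrying rho * a0
    out, _ = lfilter([1.0], [1.0, -rho], innov, zi=[rho * a0])
    return out


def generate_weather(station_spec, start_date, end_date, base: float = 15.0,
                     amplitude: float = 12.0, peak_doy: float = 196.0,
                     ar1_rho: float = 0.7, noise_sd: float = 3.0,
                     dewpoint_offset: float = 8.0, dewpoint_noise_sd: float = 2.0,
                     seed=None) -> pd.DataFrame:
    """Daily Tmax and dew point for each station in ``station_spec``.

    ``station_spec`` is a list of ``(station_id, lat, lon)``.  Tmax is the
    seasonal sinusoid plus a stationary AR(1) anomaly (lag-1 correlation
    ``ar1_rho``, innovation SD ``noise_sd``); dew point tracks Tmax minus
    ``dewpoint_offset`` plus independent noise.  Returns a tidy frame with
    columns station_id, latitude, longitude, date, tmax, dew_point.
    """
    if abs(ar1_rho) >= 1:
        raise ValueError("ar1_rho must satisfy |rho| < 1 (stationarity)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dates = _date_index(start_date, end_date)
    rng = np.random.default_rng(seed)
    frames = []
    for sid, lat, lon in station_spec:
        mean = seasonal_mean(dates.day_of_year, base, amplitude, peak_doy)
        tmax = mean + _ar1(rng, len(dates), ar1_rho, noise_sd)
        dew = tmax - dewpoint_offset + (
            rng.normal(0.0, dewpoint_noise_sd, len(dates)) if dewpoint_noise_sd > 0 else 0.0)
        frames.append(pd.DataFrame({
            "station_id": str(sid), "latitude": lat, "longitude": lon,
            "date": dates.date, "tmax": tmax, "dew_point": dew,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_monitors(monitor_spec, start_date, end_date, mean_level: float = 12.0,
                      seasonal_amplitude: float = 3.0, peak_doy: float = 200.0,
                      log_noise_sd: float = 0.4, missing_rate: float = 0.1,
                      seed=None) -> pd.DataFrame:
    """Daily 24-h mean PM2.5 per monitor: a seasonal mean times a mean-one
    log-normal factor, with a ``missing_rate`` fraction of days absent.

    Returns a tidy frame with columns monitor_id, latitude, longitude, date,
    pm25 (missing days are dropped, not NaN-filled).
    """
    if mean_level <= 0:
        raise ValueError("mean_level must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if seasonal_amplitude >= mean_level:
        raise ValueError("seasonal_amplitude must be below mean_level (pm25 >= 0)")
    dates = _date_index(start_date, end_date)
    rng = np.random.default_rng(seed)
    frames = []
    for mid, lat, lon in monitor_spec:
        mean = seasonal_mean(dates.day_of_year, mean_level, seasonal_amplitude, peak_doy)
        if log_noise_sd > 0:
            factor = np.exp(rng.normal(0.0, log_noise_sd, len(dates)) - log_noise_sd**2 / 2.0)
        else:
            factor = 1.0
        pm = mean * factor
        keep = rng.random(len(dates)) >= missing_rate
        frames.append(pd.DataFrame({
            "monitor_id": str(mid), "latitude": lat, "longitude": lon,
            "date": dates.date[keep], "pm25": pm[keep],
        }))
    return pd.concat(frames, ignore_index=True)


def _draw_categorical(rng, probs: dict, n: int) -> np.ndarray:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("covariate probabilities must sum to 1")
    return rng.choice(cats, size=n, p=p)


def generate_subjects(n: int, residence_box=(30.0, 36.0, -100.0, -90.0),
                      edd_range=(dt.date(1999, 1, 1), dt.date(2007, 12, 31)),
                      covariate_probs=None, climate_region: str = "South",
                      gest_age_mean: float = 39.0, gest_age_sd: float = 2.0,
                      residence_shift_by_race=None, seed=None) -> pd.DataFrame:
    """A cohort of pregnancies with residences, delivery dates and covariates.

    EDDs are uniform over ``edd_range`` so conceptions span all seasons;
    covariates are drawn independently.  ``residence_shift_by_race`` is an
    optional confounding hook mapping a race/ethnicity category to a
    ``(dlat, dlon)`` mean shift of residence, letting tests create
    covariate-dependent exposure.  Case status is left unset.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lat_min, lat_max, lon_min, lon_max = residence_box
    start, end = pd.Timestamp(edd_range[0]), pd.Timestamp(edd_range[1])
    if start > end:
        raise ValueError("empty EDD range")
    probs = covariate_probs or DEFAULT_COVARIATE_PROBS
    rng = np.random.default_rng(seed)

    lat = rng.uniform(lat_min, lat_max, n)
    lon = rng.uniform(lon_min, lon_max, n)
    race = _draw_categorical(rng, probs["race_ethnicity"], n)
    if residence_shift_by_race:
        for cat, (dlat, dlon) in residence_shift_by_race.items():
            m = race == cat
            lat[m] = np.clip(lat[m] + dlat, lat_min, lat_max)
            lon[m] = np.clip(lon[m] + dlon, lon_min, lon_max)
    offsets = rng.integers(0, (end - start).days + 1, n)
    edd = np.array([(start + pd.Timedelta(days=int(o))).date() for o in offsets])
    gest = np.clip(np.rint(rng.normal(gest_age_mean, gest_age_sd, n)), 20, 44).astype(int)
    return pd.DataFrame({
        "subject_id": [f"S{i:06d}" for i in range(1, n + 1)],
        "is_case": pd.array([pd.NA] * n, dtype="boolean"),
        "outcome_group": pd.array([pd.NA] * n, dtype="string"),
        "latitude": lat, "longitude": lon,
        "edd": edd, "gestational_age_weeks": gest,
        "maternal_age_cat": _draw_categorical(rng, probs["maternal_age_cat"], n),
        "education_cat": _draw_categorical(rng, probs["education_cat"], n),
        "race_ethnicity": race,
        "climate_region": climate_region,
    })


def _linear_predictor(df: pd.DataFrame, model: TrueModel,
                      pm_col: str, ehe_col: str) -> np.ndarray:
    pm = df[pm_col].astype(bool).to_numpy(dtype=float)
    ehe = df[ehe_col].astype(bool).to_numpy(dtype=float)
    lp = model.intercept + model.beta_pm * pm + model.beta_ehe * ehe \
        + model.beta_interaction * pm * ehe
    if model.covariate_betas:
        dummies = covariate_dummies(df)
        for name, beta in model.covariate_betas.items():
            lp = lp + beta * dummies[name].to_numpy(dtype=float)
    return lp


def assign_outcomes(subjects: pd.DataFrame, exposures: pd.DataFrame, model: TrueModel,
                    seed=None, outcome_label: str = "case",
                    pm_col: str = "pm_high", ehe_col: str = "ehe95_exposed") -> pd.DataFrame:
    """Draw Bernoulli case status from the generative logistic model.

    ``exposures`` must carry ``pm_col`` and ``ehe_col`` (non-missing) for
    every subject; cases get ``outcome_label``, non-cases become controls.
    """
    missing = set(subjects["subject_id"]) - set(exposures["subject_id"])
    if missing:
        raise ValueError(f"missing exposure records for {len(missing)} subjects")
    merged = subjects.merge(
        exposures[["subject_id", pm_col, ehe_col] +
                  (["mean_dew_point"] if "mean_dew_point" in exposures.columns else [])],
        on="subject_id", how="left", validate="one_to_one")
    if merged[pm_col].isna().any() or merged[ehe_col].isna().any():
        raise ValueError("exposure record incomplete for some subjects "
                         f"({pm_col}/{ehe_col} missing)")
    if "mean_dew_point" not in merged.columns:
        merged["mean_dew_point"] = 0.0
    rng = np.random.default_rng(seed)
    p = expit(_linear_predictor(merged, model, pm_col, ehe_col))
    is_case = rng.random(len(merged)) < p
    out = subjects.copy()
    out["is_case"] = pd.array(is_case, dtype="boolean")
    out["outcome_group"] = pd.array(
        np.where(is_case, outcome_label, "control"), dtype="string")
    return out


def sample_case_control(cohort: pd.DataFrame, n_cases: int, n_controls: int,
                        seed=None) -> pd.DataFrame:
    """Outcome-dependent sampling without replacement (unmatched design).

    Only the intercept is biased by design; exposure odds ratios are
    preserved in expectation.
    """
    is_case = cohort["is_case"].astype(bool).to_numpy()
    case_idx = cohort.index[is_case]
    control_idx = cohort.index[~is_case]
    if len(case_idx) < n_cases:
        raise ValueError(f"cohort has {len(case_idx)} cases; {n_cases} requested")
    if len(control_idx) < n_controls:
        raise ValueError(f"cohort has {len(control_idx)} controls; {n_controls} requested")
    rng = np.random.default_rng(seed)
    take = np.concatenate([
        rng.choice(case_idx, size=n_cases, replace=False),
        rng.choice(control_idx, size=n_controls, replace=False),
    ])
    return cohort.loc[np.sort(take)].reset_index(drop=True)


def simulate_analytic_table(n_cases: int, n_controls: int, model: TrueModel,
                            p_pm: float = 0.2, p_ehe: float = 0.35,
                            covariate_probs=None, dew_mean: float = 12.0,
                            dew_sd: float = 4.0, seed=None,
                            ehe_col: str = "ehe95_exposed") -> pd.DataFrame:
    """Case-control table drawn directly at the analytic (exposure) level.

    Skips the weather/monitor machinery: pm_high and the heat-event flag are
    independent Bernoulli draws, covariates follow their marginals, and case
    status follows ``model``.  A cohort is grown in chunks until the
    requested counts exist, then sampled without replacement.  Used by the
    simulation studies (test-size calibration, CI coverage, recovery).
    """
    rng = np.random.default_rng(seed)
    probs = covariate_probs or DEFAULT_COVARIATE_PROBS

    def draw_chunk(m: int) -> pd.DataFrame:
        df = pd.DataFrame({
            "pm_high": rng.random(m) < p_pm,
            ehe_col: rng.random(m) < p_ehe,
            "maternal_age_cat": _draw_categorical(rng, probs["maternal_age_cat"], m),
            "education_cat": _draw_categorical(rng, probs["education_cat"], m),
            "race_ethnicity": _draw_categorical(rng, probs["race_ethnicity"], m),
            "mean_dew_point": rng.normal(dew_mean, dew_sd, m),
        })
        # nested warm-season flags: summer days imply a spring/summer day
        u = rng.random(m)
        df["entire_window_spring_summer"] = u < 0.25
        df["any_day_spring_summer"] = u < 0.60
        df["any_day_summer"] = df["any_day_spring_summer"] & (rng.random(m) < 0.55)
        p = expit(_linear_predictor(df, model, "pm_high", ehe_col))
        df["is_case"] = rng.random(m) < p
        return df

    needed = n_cases + n_controls
    chunks = [draw_chunk(max(4 * needed, 2000))]
    for _ in range(30):
        pool = pd.concat(chunks, ignore_index=True)
        if (pool["is_case"].sum() >= n_cases
                and (~pool["is_case"]).sum() >= n_controls):
            break
        chunks.append(draw_chunk(max(4 * needed, 2000)))
    else:
        raise RuntimeError("could not realize requested case/control counts; "
                           "intercept implies too extreme a prevalence")
    pool["outcome_group"] = np.where(pool["is_case"], "case", "control")
    pool["subject_id"] = [f"S{i:07d}" for i in range(1, len(pool) + 1)]
    sampled = sample_case_control(pool, n_cases, n_controls,
                                  seed=rng.integers(0, 2**31 - 1))
    return sampled.reset_index(drop=True)
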