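"""Pipeline stages (simulate -> expose -> analyze) and CSV contracts.

Each stage reads and writes plain CSV so any input can be replaced by real
data without code changes.  Every output file starts with ``#``-prefixed
provenance lines (package version, seed, config echo); readers here skip
them, and so does ``pandas.read_csv(..., comment="#")``.

CSV headers
-----------
weather:   station_id, latitude, longitude, date, tmax, dew_point
monitors:  monitor_id, latitude, longitude, date, pm25
subjects:  subject_id, is_case, outcome_group, latitude, longitude, edd,
           gestational_age_weeks, maternal_age_cat, education_cat,
           race_ethnicity, climate_region
exposure:  subject columns + window dates, monitor/station linkage, mean
           PM2.5 and dew point, pm_high, per-definition heat flags, season
           flags, exclusion_reason
results:   one row per (outcome_group x population_filter x ehe_definition)
           model cell (see stats.run_analysis)

Dates are ISO-8601 throughout.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exposure import DEFAULT_MIN_PM_DAYS, build_exposure_table
from .heat import CANONICAL_DEFINITIONS, EHEDefinition
from .simulate import (
    TrueModel,
    assign_outcomes,
    generate_monitors,
    generate_subjects,
    generate_weather,
    sample_case_control,
)
from .stats import POPULATION_FILTERS, run_analysis

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    # simulation stage
    n_subjects: int = 4000
    n_cases: int = 1000
    n_controls: int = 2000
    n_stations: int = 6
    n_monitors: int = 15
    start_date: str = "1999-01-01"
    end_date: str = "2003-12-31"
    edd_start: str = "2000-01-01"
    edd_end: str = "2003-06-30"
    # compact study area so most residences fall within 50 km of a monitor,
    # as in the source study's analytic population
    residence_box: tuple = (31.0, 34.0, -98.0, -95.0)
    true_intercept: float = -1.2
    true_or_pm: float = 1.0
    true_or_ehe: float = 1.3
    true_or_pm_given_ehe: float = 1.6
    # exposure stage
    weather_csv: str | None = None
    monitors_csv: str | None = None
    subjects_csv: str | None = None
    ehe_definitions: tuple = ("EHE95", "EHE90")
    pm_percentile: float = 80.0
    min_pm_days: int = DEFAULT_MIN_PM_DAYS
    max_monitor_km: float = 50.0
    # analysis stage
    exposure_csv: str | None = None
    outcome_groups: tuple = ("case",)
    population_filters: tuple = tuple(POPULATION_FILTERS)
    lrt_alpha: float = 0.1
    profile_ci: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("residence_box", "ehe_definitions", "outcome_groups", "population_filters"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _definitions(names) -> list[EHEDefinition]:
    by_name = {d.name: d for d in CANONICAL_DEFINITIONS}
    out = []
    for name in names:
        if name not in by_name:
            raise KeyError(f"unknown EHE definition {name!r}; known: {sorted(by_name)}")
        out.append(by_name[name])
    return out


def _provenance(config: PipelineConfig, stage: str) -> str:
    echo = yaml.safe_dump(dataclasses.asdict(config), default_flow_style=True, width=10_000).strip()
    return (f"# heatpm {__version__} | stage={stage} | seed={config.seed}\n"
            f"# config: {echo}\n")


def write_csv(df: pd.DataFrame, path, config: PipelineConfig, stage: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config, stage))
        df.to_csv(fh, index=False)
    return path


def read_csv(path, date_cols=()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in date_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.date
    return df


def read_weather(path):
    return read_csv(path, date_cols=("date",))


def read_monitors(path):
    return read_csv(path, date_cols=("date",))


def read_subjects(path):
    df = read_csv(path, date_cols=("edd",))
    if "is_case" in df.columns:
        df["is_case"] = df["is_case"].astype("boolean")
    return df


def cmd_simulate(config: PipelineConfig) -> dict:
    """Write weather, monitor and subject CSVs plus a true-parameter manifest.

    The generative truth sets the PM2.5 odds ratio to ``true_or_pm`` without
    a heat event and ``true_or_pm_given_ehe`` with one; recovery tests read
    the manifest back.
    """
    if config.n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    out = Path(config.out_dir)
    seed = config.seed
    lat0, lat1, lon0, lon1 = config.residence_box

    import numpy as np
    rng = np.random.default_rng(seed)
    stations = [(f"ST{i:02d}", rng.uniform(lat0, lat1), rng.uniform(lon0, lon1))
                for i in range(config.n_stations)]
    monitors = [(f"M{i:03d}", rng.uniform(lat0, lat1), rng.uniform(lon0, lon1))
                for i in range(config.n_monitors)]

    weather = generate_weather(stations, config.start_date, config.end_date, seed=seed + 1)
    monitor_df = generate_monitors(monitors, config.start_date, config.end_date, seed=seed + 2)
    subjects = generate_subjects(
        config.n_subjects, residence_box=config.residence_box,
        edd_range=(pd.Timestamp(config.edd_start).date(), pd.Timestamp(config.edd_end).date()),
        seed=seed + 3)

    model = TrueModel(
        intercept=config.true_intercept,
        beta_pm=float(np.log(config.true_or_pm)),
        beta_ehe=float(np.log(config.true_or_ehe)),
        beta_interaction=float(np.log(config.true_or_pm_given_ehe / config.true_or_pm)),
    )
    # exposures under the truth, then outcome assignment and case-control sampling
    exposure, threshold = build_exposure_table(
        subjects, weather, monitor_df,
        ehe_definitions=_definitions(config.ehe_definitions),
        min_pm_days=config.min_pm_days, pm_percentile=config.pm_percentile,
        max_monitor_km=config.max_monitor_km)
    linkable = exposure[exposure["pm_high"].notna()]
    cohort = assign_outcomes(
        subjects[subjects["subject_id"].isin(linkable["subject_id"])].reset_index(drop=True),
        linkable, model, seed=seed + 4)
    n_cases = min(config.n_cases, int(cohort["is_case"].sum()))
    n_controls = min(config.n_controls, int((~cohort["is_case"].astype(bool)).sum()))
    logger.info("cohort of %d: sampling %d cases, %d controls", len(cohort), n_cases, n_controls)
    study = sample_case_control(cohort, n_cases, n_controls, seed=seed + 5)

    paths = {
        "weather": write_csv(weather, out / "weather.csv", config, "simulate"),
        "monitors": write_csv(monitor_df, out / "monitors.csv", config, "simulate"),
        "subjects": write_csv(study, out / "subjects.csv", config, "simulate"),
    }
    manifest = {
        "seed": seed, "n_cases": n_cases, "n_controls": n_controls,
        "generation_pm_threshold": float(threshold),
        "true_model": {
            "intercept": model.intercept, "beta_pm": model.beta_pm,
            "beta_ehe": model.beta_ehe, "beta_interaction": model.beta_interaction,
            "true_reri": model.true_reri(),
            "true_stratum_ors": list(model.true_stratum_ors()),
        },
    }
    manifest_path = out / "true_params.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest))
    paths["manifest"] = manifest_path
    return paths


def cmd_expose(config: PipelineConfig) -> Path:
    """Derive the per-subject exposure table from the three input CSVs."""
    out = Path(config.out_dir)
    subjects = read_subjects(config.subjects_csv or out / "subjects.csv")
    weather = read_weather(config.weather_csv or out / "weather.csv")
    monitors = read_monitors(config.monitors_csv or out / "monitors.csv")
    exposure, threshold = build_exposure_table(
        subjects, weather, monitors,
        ehe_definitions=_definitions(config.ehe_definitions),
        min_pm_days=config.min_pm_days, pm_percentile=config.pm_percentile,
        max_monitor_km=config.max_monitor_km)
    logger.info("PM2.5 threshold (control %gth percentile): %.3f ug/m3",
                config.pm_percentile, threshold)
    merged = subjects.merge(exposure, on="subject_id", validate="one_to_one")
    return write_csv(merged, out / "exposure.csv", config, "expose")


def cmd_analyze(config: PipelineConfig) -> dict:
    """Fit every model cell and write the tidy results table plus a report."""
    out = Path(config.out_dir)
    path = config.exposure_csv or out / "exposure.csv"
    df = read_csv(path, date_cols=("edd", "conception", "window_start", "window_end"))
    for col in [c for c in df.columns if c.endswith("_exposed")] + [
            "pm_high", "any_day_spring_summer", "entire_window_spring_summer",
            "any_day_summer"]:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    df["is_case"] = df["is_case"].astype("boolean")
    if df["is_case"].astype(bool).sum() == 0 or (~df["is_case"].astype(bool)).sum() == 0:
        raise ValueError("empty analytic population: need both cases and controls")

    results = run_analysis(
        df, outcome_groups=config.outcome_groups,
        ehe_definitions=config.ehe_definitions,
        population_filters=config.population_filters,
        alpha=config.lrt_alpha, profile_ci=config.profile_ci)
    results_path = write_csv(results, out / "results.csv", config, "analyze")

    lines = [_provenance(config, "analyze").rstrip()]
    for row in results.itertuples(index=False):
        if row.status != "ok":
            lines.append(f"{row.outcome_group}/{row.population_filter}/{row.ehe_definition}: "
                         f"{row.status}")
            continue
        lines.append(
            f"{row.outcome_group}/{row.population_filter}/{row.ehe_definition}: "
            f"OR(PM|no EHE)={row.or_pm_no_ehe:.2f} "
            f"({row.or_pm_no_ehe_lo:.2f},{row.or_pm_no_ehe_hi:.2f}); "
            f"OR(PM|EHE)={row.or_pm_ehe:.2f} "
            f"({row.or_pm_ehe_lo:.2f},{row.or_pm_ehe_hi:.2f}); "
            f"LRT p={row.lrt_p:.3f}{' *' if row.modification_flag else ''}; "
            f"RERI={row.reri:.2f} "
            f"(likelihood {row.reri_prof_lo:.2f},{row.reri_prof_hi:.2f})")
    report_path = out / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    return {"results": results_path, "report": report_path}
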