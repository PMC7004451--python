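"""Gestational exposure windows and environmental linkage.

Converts estimated delivery dates into the weeks-3--8 critical window of
cardiogenesis, links maternal residences to the nearest PM2.5 monitor (within
50 km) and weather station, computes window-average PM2.5 and dew point,
dichotomizes PM2.5 at the control 80th percentile, and derives season flags
used to define warm-season subpopulations.

Conventions
-----------
* Conception is estimated as EDD minus 266 days (38 postconceptional weeks,
  the standard clinical convention).  An alternative reconstruction from the
  recorded gestational age is available via ``conception_from_delivery``.
* Postconceptional day 1 is the first day after conception; week k covers
  days 7(k-1)+1..7k, so weeks 3--8 span days 15--56 -- a 42-day window.
* Percentiles use linear interpolation between order statistics at
  h = (n-1)p + 1 (numpy's default), so thresholds are bit-reproducible.
* ``pm_high`` uses a strict inequality (mean strictly above the threshold);
  values tied with the threshold are classified low.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

GESTATION_DAYS = 266
WINDOW_START_OFFSET = 14  # postconceptional day 15
WINDOW_END_OFFSET = 55  # postconceptional day 56
WINDOW_LENGTH_DAYS = WINDOW_END_OFFSET - WINDOW_START_OFFSET + 1
PM_MAX_DISTANCE_KM = 50.0
EARTH_RADIUS_KM = 6371.0
DEFAULT_MIN_PM_DAYS = 28  # two-thirds of the 42-day window

_SEASON_BY_MONTH = {
    1: "winter", 2: "winter", 12: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


@dataclass(frozen=True)
class CriticalWindow:
    """Weeks 3--8 of pregnancy, both endpoints inclusive."""

    conception: dt.date
    start: dt.date
    end: dt.date

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(self.n_days)]


def _as_date(d) -> dt.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


def conception_date(edd) -> dt.date:
    """Estimated conception date: EDD minus 266 days."""
    return _as_date(edd) - dt.timedelta(days=GESTATION_DAYS)


def conception_from_delivery(delivery_date, gestational_age_weeks: int) -> dt.date:
    """Alternative mode: conception from actual delivery date and recorded
    gestational age (gestational weeks counted from conception)."""
    return _as_date(delivery_date) - dt.timedelta(days=7 * int(gestational_age_weeks))


def critical_window(conception) -> CriticalWindow:
    """The 42-day window spanning postconceptional days 15--56."""
    c = _as_date(conception)
    return CriticalWindow(
        conception=c,
        start=c + dt.timedelta(days=WINDOW_START_OFFSET),
        end=c + dt.timedelta(days=WINDOW_END_OFFSET),
    )


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (Earth radius 6371 km).

    Accepts scalars or numpy arrays of decimal degrees.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


def nearest_site(lat, lon, sites: pd.DataFrame, id_col: str, max_km: float | None = None):
    """Nearest site to a residence; ``None`` if the minimum exceeds ``max_km``.

    ``sites`` must have columns ``id_col``, ``latitude``, ``longitude``.
    Exact distance ties are broken by the lexicographically smallest site id.
    """
    if len(sites) == 0:
        raise ValueError("site list is empty")
    d = haversine_km(lat, lon, sites["latitude"].to_numpy(), sites["longitude"].to_numpy())
    d = np.atleast_1d(d)
    ids = sites[id_col].astype(str).to_numpy()
    order = np.lexsort((ids, d))
    best = order[0]
    if max_km is not None and d[best] > max_km:
        return None
    return ids[best], float(d[best])


def window_mean(series: pd.Series, window: CriticalWindow, min_days: int = 1):
    """Mean of a daily series over the window's available days.

    ``series`` is indexed by date.  Returns ``(mean, n_days)``; mean is NaN
    when fewer than ``min_days`` in-window days are available.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    idx = pd.to_datetime(series.index)
    mask = (idx >= pd.Timestamp(window.start)) & (idx <= pd.Timestamp(window.end))
    vals = pd.to_numeric(series[mask], errors="coerce").dropna()
    n = int(len(vals))
    if n < min_days:
        return float("nan"), n
    return float(vals.mean()), n


def season_of(date) -> str:
    """Meteorological season: MAM spring, JJA summer, SON autumn, DJF winter."""
    return _SEASON_BY_MONTH[_as_date(date).month]


def season_flags(window: CriticalWindow) -> tuple[bool, bool, bool]:
    """(any day in spring/summer, entire window in spring/summer, any day in summer)."""
    seasons = {season_of(d) for d in window.dates()}
    warm = {"spring", "summer"}
    any_ss = bool(seasons & warm)
    entire_ss = seasons <= warm
    any_summer = "summer" in seasons
    return any_ss, entire_ss, any_summer


def control_percentile_threshold(values: pd.Series, percentile: float = 80.0) -> float:
    vals = pd.to_numeric(values, errors="coerce").dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError("need at least 2 controls with PM2.5 data")
    return float(np.percentile(vals, percentile))


def dichotomize_pm(
    table: pd.DataFrame,
    control_mask,
    percentile: float = 80.0,
    pm_col: str = "mean_pm25",
) -> tuple[pd.DataFrame, float]:
    """Flag window means strictly above the control ``percentile`` threshold.

    The threshold is computed from controls only, so adding or removing case
    rows never moves it.  Returns the table with a nullable-boolean
    ``pm_high`` column (missing wherever ``mean_pm25`` is missing) and the
    threshold itself.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    threshold = control_percentile_threshold(table.loc[control_mask, pm_col], percentile)
    out = table.copy()
    pm = pd.to_numeric(out[pm_col], errors="coerce")
    high = pd.array(pm > threshold, dtype="boolean")
    high[pm.isna()] = pd.NA
    out["pm_high"] = high
    return out, threshold


def build_exposure_table(
    subjects: pd.DataFrame,
    weather: pd.DataFrame,
    monitors: pd.DataFrame,
    ehe_definitions=None,
    min_pm_days: int = DEFAULT_MIN_PM_DAYS,
    pm_percentile: float = 80.0,
    max_monitor_km: float = PM_MAX_DISTANCE_KM,
    control_label: str = "control",
):
    """Derive one exposure record per subject and the PM2.5 threshold.

    Subjects failing monitor linkage or PM coverage stay in the table with
    missing PM fields and an ``exclusion_reason``; the weather-station link is
    uncapped.  Returns ``(exposure_table, pm_threshold)``.  The threshold is
    computed among rows whose ``outcome_group`` equals ``control_label`` (all
    rows if case status is entirely unset, the generative-cohort case).
    """
    from .heat import CANONICAL_DEFINITIONS, detect_events, window_ehe_exposure

    if ehe_definitions is None:
        ehe_definitions = CANONICAL_DEFINITIONS

    monitor_sites = monitors[["monitor_id", "latitude", "longitude"]].drop_duplicates("monitor_id")
    station_sites = weather[["station_id", "latitude", "longitude"]].drop_duplicates("station_id")

    pm_by_monitor = {
        mid: grp.set_index("date")["pm25"].sort_index()
        for mid, grp in monitors.groupby("monitor_id")
    }
    weather_by_station = {
        sid: grp.set_index("date").sort_index() for sid, grp in weather.groupby("station_id")
    }
    events_cache: dict[tuple[str, str], list] = {}

    rows = []
    for subj in subjects.itertuples(index=False):
        window = critical_window(conception_date(subj.edd))
        any_ss, entire_ss, any_summer = season_flags(window)
        rec = {
            "subject_id": subj.subject_id,
            "conception": window.conception,
            "window_start": window.start,
            "window_end": window.end,
            "monitor_id": None,
            "monitor_distance_km": np.nan,
            "n_pm_days": 0,
            "mean_pm25": np.nan,
            "station_id": None,
            "station_distance_km": np.nan,
            "mean_dew_point": np.nan,
            "any_day_spring_summer": any_ss,
            "entire_window_spring_summer": entire_ss,
            "any_day_summer": any_summer,
            "exclusion_reason": "",
        }
        hit = nearest_site(subj.latitude, subj.longitude, monitor_sites, "monitor_id", max_km=max_monitor_km)
        if hit is None:
            rec["exclusion_reason"] = "no_monitor_within_50km"
        else:
            mid, dist = hit
            rec["monitor_id"], rec["monitor_distance_km"] = mid, dist
            mean_pm, n_days = window_mean(pm_by_monitor[mid], window, min_days=min_pm_days)
            rec["n_pm_days"] = n_days
            rec["mean_pm25"] = mean_pm
            if np.isnan(mean_pm):
                rec["exclusion_reason"] = "insufficient_pm_days"

        sid, sdist = nearest_site(subj.latitude, subj.longitude, station_sites, "station_id")
        rec["station_id"], rec["station_distance_km"] = sid, sdist
        sw = weather_by_station[sid]
        rec["mean_dew_point"], _ = window_mean(sw["dew_point"], window, min_days=1)
        for definition in ehe_definitions:
            key = (sid, definition.name)
            if key not in events_cache:
                events_cache[key] = detect_events(
                    weather.loc[weather["station_id"] == sid], definition
                )
            rec[f"{definition.name.lower()}_exposed"] = window_ehe_exposure(window, events_cache[key])
        rows.append(rec)

    table = pd.DataFrame(rows)
    if "outcome_group" in subjects.columns and subjects["outcome_group"].notna().any():
        controls = subjects.set_index("subject_id")["outcome_group"].eq(control_label)
        control_mask = table["subject_id"].map(controls).fillna(False).to_numpy()
    else:
        control_mask = np.ones(len(table), dtype=bool)
    table, threshold = dichotomize_pm(table, control_mask, percentile=pm_percentile)
    return table, threshold
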