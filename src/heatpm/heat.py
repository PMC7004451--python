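"""Extreme-heat-event (EHE) detection from daily station Tmax series.

An EHE is a maximal run of consecutive calendar days whose daily maximum
temperature is strictly above a season-and-year-specific percentile of that
station's Tmax distribution.  Two canonical definitions are supported:

* EHE95 -- at least 2 consecutive days above the seasonal 95th percentile;
* EHE90 -- at least 3 consecutive days above the seasonal 90th percentile.

Runs never cross season boundaries (the threshold itself is season-specific)
and are broken by missing days: a run cannot be certified across unobserved
days.  The year of a DJF winter is the January year, so December belongs to
the following winter.  A season-year with fewer than ``min_days`` observed
Tmax values has no threshold and is skipped with a warning.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import CriticalWindow, _as_date, season_of

logger = logging.getLogger(__name__)

MIN_SEASON_DAYS = 10


@dataclass(frozen=True)
class EHEDefinition:
    name: str
    q: float  # percentile of the season-year Tmax distribution
    min_run: int  # minimum consecutive qualifying days

    def __post_init__(self):
        if not 0 < self.q < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


EHE95 = EHEDefinition("EHE95", 95.0, 2)
EHE90 = EHEDefinition("EHE90", 90.0, 3)
CANONICAL_DEFINITIONS = (EHE95, EHE90)


@dataclass(frozen=True)
class HeatEvent:
    station_id: str
    start: dt.date
    end: dt.date
    definition: str
    season: str
    year: int

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


def season_year(date) -> tuple[str, int]:
    """(season, season-year); December belongs to the next January's winter."""
    d = _as_date(date)
    season = season_of(d)
    year = d.year + 1 if d.month == 12 else d.year
    return season, year


def seasonal_threshold(series: pd.DataFrame, season: str, year: int, q: float,
                       min_days: int = MIN_SEASON_DAYS):
    """Percentile threshold of a station's Tmax for one season-year.

    ``series`` has columns ``date`` and ``tmax``.  Returns ``None`` (with a
    logged warning) when fewer than ``min_days`` non-missing values exist.
    """
    keys = [season_year(d) for d in series["date"]]
    mask = np.array([k == (season, year) for k in keys])
    vals = pd.to_numeric(series.loc[mask, "tmax"], errors="coerce").dropna().to_numpy()
    if len(vals) < min_days:
        logger.warning("insufficient Tmax data for %s %d (%d days); threshold undefined",
                       season, year, len(vals))
        return None
    return float(np.percentile(vals, q))


def _find_runs(dates, tmax, threshold: float, min_run: int):
    """Maximal runs of consecutive calendar days with tmax strictly above
    ``threshold``; runs of length < ``min_run`` are dropped.

    Missing (NaN) days and calendar gaps break runs.  Returns a list of
    (start_date, end_date) pairs.
    """
    runs = []
    start = prev = None
    for d, t in zip(dates, tmax):
        d = _as_date(d)
        qualifies = t is not None and np.isfinite(t) and t > threshold
        contiguous = prev is not None and (d - prev).days == 1
        if qualifies and start is not None and contiguous:
            pass  # run continues
        elif qualifies:
            if start is not None and (prev - start).days + 1 >= min_run:
                runs.append((start, prev))
            start = d
        else:
            if start is not None and (prev - start).days + 1 >= min_run:
                runs.append((start, prev))
            start = None
        if qualifies:
            prev = d
        else:
            prev = None
    if start is not None and (prev - start).days + 1 >= min_run:
        runs.append((start, prev))
    return runs


def detect_events(series: pd.DataFrame, definition: EHEDefinition,
                  min_days: int = MIN_SEASON_DAYS) -> list[HeatEvent]:
    """All heat events for one station under ``definition``.

    ``series`` has columns ``station_id``, ``date``, ``tmax`` (one station).
    Each season-year segment is scanned independently against its own
    threshold, so a hot spell straddling a season boundary yields separate
    events (or none) on either side.
    """
    if series.empty:
        return []
    station_ids = series["station_id"].unique()
    if len(station_ids) != 1:
        raise ValueError("detect_events expects a single station's series")
    station_id = str(station_ids[0])

    df = series.sort_values("date")
    dates = [_as_date(d) for d in df["date"]]
    tmax = pd.to_numeric(df["tmax"], errors="coerce").to_numpy()
    sy = [season_year(d) for d in dates]

    events: list[HeatEvent] = []
    for key in sorted(set(sy), key=lambda k: (k[1], dates[sy.index(k)])):
        season, year = key
        idx = [i for i, k in enumerate(sy) if k == key]
        seg_dates = [dates[i] for i in idx]
        seg_tmax = tmax[idx]
        finite = seg_tmax[np.isfinite(seg_tmax)]
        if len(finite) < min_days:
            logger.warning("skipping %s %s %d: only %d observed days",
                           station_id, season, year, len(finite))
            continue
        threshold = float(np.percentile(finite, definition.q))
        for start, end in _find_runs(seg_dates, seg_tmax, threshold, definition.min_run):
            events.append(HeatEvent(station_id, start, end, definition.name, season, year))
    events.sort(key=lambda e: e.start)
    return events


def window_ehe_exposure(window: CriticalWindow, events) -> bool:
    """True iff at least one event day falls inside the window (any overlap)."""
    ws, we = window.start, window.end
    return any(e.start <= we and e.end >= ws for e in events)


def events_to_frame(events) -> pd.DataFrame:
    """Events as a BED-like table (station, start, end, definition, season, year)."""
    cols = ["station_id", "start", "end", "definition", "season", "year"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events], columns=cols)
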