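"""Temporal predictors: period averaging of daily series, season coding and
the calendar time trend.

Passive-sampler measurements integrate over a period (14 days in the rural
network, calendar months in the urban one); every daily series (background
NO2 from the air-quality monitoring station, meteorology from the assigned
station) is averaged over the same period.  Season is an ordinal code on the
period midpoint: 1 summer (May-Aug), 2 mid-season (Mar, Apr, Sep, Oct),
3 winter (Nov-Feb).  The time trend is the decimal year of the period
midpoint; its square may enter the model as a ``square(year)`` term.
"""

from __future__ import annotations

import calendar
import datetime as dt

import numpy as np
import pandas as pd

__all__ = [
    "MissingDataError",
    "period_mean",
    "season_of",
    "decimal_year",
    "time_trend",
    "period_midpoint",
    "temporal_predictor_table",
]

TEMPORAL_VARIABLES = (
    "aqm_no2",
    "temperature",
    "pressure",
    "humidity",
    "wind_speed",
    "cloud_cover",
    "solar_radiation",
    "boundary_layer_height",
)

#: month -> ordinal season code
_SEASON_BY_MONTH = {
    1: 3, 2: 3, 3: 2, 4: 2, 5: 1, 6: 1,
    7: 1, 8: 1, 9: 2, 10: 2, 11: 3, 12: 3,
}


class MissingDataError(ValueError):
    """A measurement period is insufficiently covered by the daily series."""


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


def period_mean(
    series: pd.Series, start, end, min_coverage: float = 0.8
) -> float:
    """Arithmetic mean of a date-indexed daily series over ``[start, end)``.

    At least ``min_coverage`` of the period's days must be present and
    non-missing, otherwise a :class:`MissingDataError` identifies the gap.
    The result does not depend on the ordering of the daily records.
    """
    start, end = _as_date(start), _as_date(end)
    if end <= start:
        raise ValueError(f"period end {end} must be after start {start}")
    n_days = (end - start).days
    idx = pd.DatetimeIndex(series.index)
    mask = (idx >= pd.Timestamp(start)) & (idx < pd.Timestamp(end))
    vals = series.to_numpy(dtype=float)[np.asarray(mask)]
    vals = vals[~np.isnan(vals)]
    if vals.size < min_coverage * n_days:
        raise MissingDataError(
            f"period {start}..{end}: only {vals.size}/{n_days} days available "
            f"(need >= {min_coverage:.0%})"
        )
    return float(vals.mean())


def period_midpoint(start, end) -> dt.date:
    """Midpoint date of ``[start, end)`` (floor on half days)."""
    start, end = _as_date(start), _as_date(end)
    return start + dt.timedelta(days=(end - start).days // 2)


def season_of(start, end=None) -> int:
    """Ordinal season of a date or of a period's midpoint.

    1 = summer (May-Aug), 2 = mid-season (Mar, Apr, Sep, Oct),
    3 = winter (Nov-Feb).  Periods straddling a boundary are coded by their
    midpoint.
    """
    d = _as_date(start) if end is None else period_midpoint(start, end)
    return _SEASON_BY_MONTH[d.month]


def decimal_year(d) -> float:
    """Decimal year of a date: year + (day-of-year - 0.5)/days-in-year."""
    d = _as_date(d)
    days = 366 if calendar.isleap(d.year) else 365
    return d.year + (d.timetuple().tm_yday - 0.5) / days


def time_trend(start, end) -> tuple[float, float]:
    """Decimal year of the period midpoint and its square."""
    yr = decimal_year(period_midpoint(start, end))
    return yr, yr * yr


def temporal_predictor_table(
    series: dict[tuple[str, str], pd.Series],
    periods: pd.DataFrame,
    station_of_site: dict[str, str],
    aqm_station: str,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Temporal predictor row per measurement period.

    Parameters
    ----------
    series
        ``(variable, station_id) -> daily series`` mapping; background NO2 is
        read from ``aqm_station``, meteorology from each site's assigned
        station.
    periods
        Frame with columns ``site_id, period_start, period_end`` (one row per
        measurement).
    station_of_site
        Nearest-meteorological-station assignment per site.

    Returns a frame aligned with ``periods`` carrying all temporal predictors
    plus ``season``, ``year`` and ``midpoint_year`` (integer calendar year of
    the midpoint, used to interpolate annual spatial layers).
    """
    met_vars = [v for v in TEMPORAL_VARIABLES if v != "aqm_no2"]
    cache: dict[tuple, float] = {}

    def mean_of(var: str, station: str, s, e) -> float:
        key = (var, station, s, e)
        if key not in cache:
            cache[key] = period_mean(series[(var, station)], s, e, min_coverage)
        return cache[key]

    rows = []
    for rec in periods.itertuples(index=False):
        s, e = _as_date(rec.period_start), _as_date(rec.period_end)
        station = station_of_site[rec.site_id]
        row = {"site_id": rec.site_id, "period_start": s, "period_end": e}
        row["aqm_no2"] = mean_of("aqm_no2", aqm_station, s, e)
        for var in met_vars:
            row[var] = mean_of(var, station, s, e)
        row["season"] = season_of(s, e)
        row["year"], _ = time_trend(s, e)
        row["midpoint_year"] = period_midpoint(s, e).year
        rows.append(row)
    return pd.DataFrame(rows)
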