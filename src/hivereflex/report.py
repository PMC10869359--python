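"""Seasonal and diurnal aggregation of per-pulse response metrics.

Presentation surfaces for long campaigns: hour-of-day x day grids of a
chosen metric (interpolated to hourly resolution), morning-only daily
averages per colony, a robust cross-colony outlier flagger (the
operational form of "the queenless colony stands out"), and the metabolic
duty-cycle arithmetic showing how little energy the assay costs the
colony.

All pulse epochs are UTC seconds; local time enters only here, through
``tz_offset`` (hours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "diurnal_grid",
    "morning_daily_average",
    "flag_outlier_colony",
    "metabolic_duty_cycle",
]


def _local_day_hour(epochs: np.ndarray, tz_offset: float) -> tuple[np.ndarray, np.ndarray]:
    local = np.asarray(epochs, dtype=float) + tz_offset * 3600.0
    day = np.floor(local / 86400.0).astype(int)
    hour = (local % 86400.0) / 3600.0
    return day, hour


def diurnal_grid(
    metrics: pd.DataFrame,
    field: str,
    tz_offset: float = 0.0,
) -> pd.DataFrame:
    """Hour-of-day x day grid of ``field``, linearly interpolated per day
    from the randomized pulse times onto integer hours.

    Rows are hours 0..23, columns day indices (days since the epoch,
    local).  Hours outside a day's first/last pulse are NaN (missing,
    never silently zero), as is any day without at least two pulses.
    """
    if field not in metrics.columns:
        raise KeyError(f"metric field {field!r} not in columns {list(metrics.columns)}")
    day, hour = _local_day_hour(metrics["pulse_epoch"].to_numpy(), tz_offset)
    values = metrics[field].to_numpy(dtype=float)
    days = np.arange(day.min(), day.max() + 1) if day.size else np.array([], dtype=int)
    grid = pd.DataFrame(np.nan, index=pd.RangeIndex(24, name="hour"), columns=days)
    grid.columns.name = "day"
    for d in days:
        m = day == d
        if m.sum() < 2:
            continue
        h = hour[m]
        v = values[m]
        order = np.argsort(h)
        h, v = h[order], v[order]
        hours_in = np.arange(24)[(np.arange(24) >= h[0]) & (np.arange(24) <= h[-1])]
        if hours_in.size:
            grid.loc[hours_in, d] = np.interp(hours_in, h, v)
    return grid


def morning_daily_average(
    metrics: pd.DataFrame,
    field: str,
    morning: tuple[float, float] = (0.0, 12.0),
    tz_offset: float = 0.0,
) -> pd.Series:
    """Per-day mean of ``field`` over pulses in the half-open local-time
    window ``[morning[0], morning[1])`` hours.  Days in the campaign span
    with no morning pulses get NaN."""
    lo, hi = morning
    day, hour = _local_day_hour(metrics["pulse_epoch"].to_numpy(), tz_offset)
    values = metrics[field].to_numpy(dtype=float)
    in_morning = (hour >= lo) & (hour < hi)
    days = np.arange(day.min(), day.max() + 1) if day.size else np.array([], dtype=int)
    out = pd.Series(np.nan, index=pd.Index(days, name="day"), name=field)
    df = pd.DataFrame({"day": day[in_morning], "v": values[in_morning]})
    if len(df):
        means = df.groupby("day")["v"].mean()
        out.loc[means.index] = means.to_numpy()
    return out


def flag_outlier_colony(
    series: dict[str, pd.Series] | pd.DataFrame,
    window_days: int = 7,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Flag colonies whose windowed mean response stands out from the
    apiary.

    For each sliding window of ``window_days`` consecutive days (step one
    day), a colony is flagged when its window mean exceeds the
    cross-colony median by more than ``z_threshold`` robust standard
    deviations (1.4826 x median absolute deviation of the colony means).
    Returns a boolean DataFrame indexed by window start day, one column
    per colony.  Requires at least three colonies.
    """
    df = pd.DataFrame(series)
    if df.shape[1] < 3:
        raise ValueError("outlier flagging requires at least 3 colonies")
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    days = df.index.to_numpy()
    starts = [d for d in days if d + window_days - 1 <= days.max()]
    flags = pd.DataFrame(False, index=pd.Index(starts, name="window_start"), columns=df.columns)
    for s in starts:
        win = df.loc[(df.index >= s) & (df.index < s + window_days)]
        means = win.mean(axis=0, skipna=True)
        if means.isna().any():
            continue
        med = float(means.median())
        mad = float((means - med).abs().median())
        robust_sd = 1.4826 * mad
        if robust_sd == 0.0:
            continue
        flags.loc[s] = (means - med) > z_threshold * robust_sd
    return flags


def metabolic_duty_cycle(response_duration: float, interval: float) -> float:
    """Percentage of time the colony spends in the elevated-metabolism
    response state: 100 * response_duration / interval.

    A 5 s response to an hourly stimulus costs at worst a 0.14% metabolic
    enhancement."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    if response_duration < 0:
        raise ValueError("response_duration must be non-negative")
    return 100.0 * response_duration / interval
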