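"""Environment characterization of drought trials from raw weather logs.

Turns timestamped air temperature / relative humidity records into daily
thermal sums (base 6 degC, daily maxima capped at 30 degC), midday vapor
pressure deficit (median VPD between 10:00 and 14:00), cumulative curves
over the trial window, and a per-trial stress index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASE_TEMP_C = 6.0
MAX_TEMP_CAP_C = 30.0
TEMP_RANGE_C = (-30.0, 50.0)
MIDDAY_WINDOW_H = (10, 14)  # [10:00, 14:00)


class ClimateError(ValueError):
    pass


@dataclass
class TrialEnvSummary:
    """End-of-trial environment summary of one experiment."""

    trial_id: str
    thermal_sum: float  # degC days at end of trial
    cum_vpd: float      # kPa, cumulative midday VPD at end of trial
    stress_index: Optional[float] = None
    water_control: Optional[float] = None  # L / plant
    water_stress: Optional[float] = None


def clean_series(raw: pd.DataFrame) -> pd.DataFrame:
    """Outlier control for a climate series.

    Removes records outside physical ranges (T outside [-30, 50] degC, RH
    outside [0, 100] %), collapses duplicate timestamps to their mean, and
    sorts by time. Removal and collapse counts are logged.
    """
    df = raw.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    n0 = len(df)
    ok = (
        df["temp_C"].between(*TEMP_RANGE_C)
        & df["rh_pct"].between(0.0, 100.0)
        & df["temp_C"].notna()
        & df["rh_pct"].notna()
    )
    df = df[ok]
    removed = n0 - len(df)
    if removed:
        log.info("clean_series: removed %d of %d records outside physical ranges",
                 removed, n0)
    if df.empty:
        raise ClimateError("climate series empty after cleaning")
    n_dup = df["timestamp"].duplicated().sum()
    if n_dup:
        value_cols = [c for c in df.columns if c != "timestamp"]
        df = df.groupby("timestamp", as_index=False)[value_cols].mean()
        log.info("clean_series: collapsed %d duplicate timestamps", n_dup)
    return df.sort_values("timestamp").reset_index(drop=True)


def vpd(temp_c, rh_pct):
    """Vapor pressure deficit (kPa) from air temperature and humidity.

    vpsat = 0.61365 * exp(17.502 * T / (240.97 + T)); vpair = vpsat * RH/100.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ClimateError("RH outside [0, 100] %")
    vpsat = 0.61365 * np.exp(17.502 * temp_c / (240.97 + temp_c))
    out = vpsat * (1.0 - rh / 100.0)
    return out if out.ndim else float(out)


def daily_thermal_sum(tmin, tmax, floor_at_zero: bool = False):
    """Daily thermal sum (degC days): (Tmin + min(Tmax, 30))/2 - 6.

    Applied literally, so the value may be negative on cold days;
    ``floor_at_zero`` switches to the conventional growing-degree-day
    floor.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ClimateError("tmin > tmax")
    out = (tmin + np.minimum(tmax, MAX_TEMP_CAP_C)) / 2.0 - BASE_TEMP_C
    if floor_at_zero:
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def hourly_means(series: pd.DataFrame) -> pd.DataFrame:
    """Average sub-hourly records to hourly means (VPD is defined on
    hourly average T and RH)."""
    value_cols = [c for c in series.columns if c != "timestamp"]
    hourly = (
        series.set_index("timestamp")[value_cols]
        .resample("h").mean()
        .dropna(subset=["temp_C", "rh_pct"])
        .reset_index()
    )
    return hourly


def daily_summaries(series: pd.DataFrame,
                    floor_at_zero: bool = False) -> pd.DataFrame:
    """Per-day Tmin, Tmax, thermal sum and midday VPD from a clean series.

    Midday VPD is the median of hourly VPD values in [10:00, 14:00); days
    without any record in that window get a missing midday VPD (logged).
    """
    hourly = hourly_means(series)
    hourly["vpd"] = vpd(hourly["temp_C"], hourly["rh_pct"])
    hourly["date"] = hourly["timestamp"].dt.normalize()
    hourly["hour"] = hourly["timestamp"].dt.hour

    rows = []
    for date, grp in hourly.groupby("date"):
        tmin = grp["temp_C"].min()
        tmax = grp["temp_C"].max()
        mid = grp[(grp["hour"] >= MIDDAY_WINDOW_H[0])
                  & (grp["hour"] < MIDDAY_WINDOW_H[1])]
        if mid.empty:
            log.info("daily_summaries: no records in midday window on %s",
                     date.date())
            midday = np.nan
        else:
            midday = float(mid["vpd"].median())
        rows.append({
            "date": date,
            "tmin": float(tmin),
            "tmax": float(tmax),
            "thermal_sum": daily_thermal_sum(tmin, tmax, floor_at_zero),
            "midday_vpd": midday,
        })
    return pd.DataFrame(rows)


def midday_vpd(series: pd.DataFrame, date) -> float:
    """Midday (10:00-14:00) median VPD for one day; NaN when the window
    holds no record."""
    dailies = daily_summaries(series)
    date = pd.Timestamp(date).normalize()
    match = dailies[dailies["date"] == date]
    if match.empty:
        return float("nan")
    return float(match["midday_vpd"].iloc[0])


def cumulative_curves(dailies: pd.DataFrame, start=None, end=None) -> pd.DataFrame:
    """Running thermal-sum and midday-VPD totals over a trial window.

    Days missing from the window contribute 0; gaps longer than 2 days
    produce a warning with a gap report.
    """
    df = dailies.copy()
    df["date"] = pd.to_datetime(df["date"])
    start = df["date"].min() if start is None else pd.Timestamp(start)
    end = df["date"].max() if end is None else pd.Timestamp(end)
    df = df[(df["date"] >= start) & (df["date"] <= end)]
    if df.empty:
        raise ClimateError("no daily summaries inside the requested window")
    full = pd.DataFrame({"date": pd.date_range(start, end, freq="D")})
    merged = full.merge(df, on="date", how="left")
    missing = merged["thermal_sum"].isna()
    if missing.any():
        gap_days = merged.loc[missing, "date"]
        runs = (gap_days.diff().dt.days.fillna(99) > 1).cumsum()
        for _, run in gap_days.groupby(runs):
            if len(run) > 2:
                log.warning("cumulative_curves: gap of %d days from %s to %s",
                            len(run), run.iloc[0].date(), run.iloc[-1].date())
    merged["cum_thermal_sum"] = merged["thermal_sum"].fillna(0.0).cumsum()
    merged["cum_vpd"] = merged["midday_vpd"].fillna(0.0).cumsum()
    return merged[["date", "thermal_sum", "midday_vpd",
                   "cum_thermal_sum", "cum_vpd"]]


def stress_index(control_sy: Iterable[float], stress_sy: Iterable[float]) -> float:
    """Trial-level stress severity: 1 - mean(stress SY)/mean(control SY),
    clamped to [0, 1]."""
    control = np.asarray(list(control_sy), dtype=float)
    stress = np.asarray(list(stress_sy), dtype=float)
    if control.size == 0 or stress.size == 0:
        raise ClimateError("stress_index needs non-empty yield vectors")
    cm = control.mean()
    if cm <= 0:
        raise ClimateError("stress_index: control mean must be positive")
    return float(np.clip(1.0 - stress.mean() / cm, 0.0, 1.0))


def trial_env_summary(trial_id: str, series: pd.DataFrame,
                      start=None, end=None,
                      control_sy=None, stress_sy=None) -> TrialEnvSummary:
    """End-of-trial summary (thermal sum, cumulative VPD, optional SI)."""
    curves = cumulative_curves(daily_summaries(clean_series(series)), start, end)
    si = None
    if control_sy is not None and stress_sy is not None:
        si = stress_index(control_sy, stress_sy)
    return TrialEnvSummary(
        trial_id=trial_id,
        thermal_sum=float(curves["cum_thermal_sum"].iloc[-1]),
        cum_vpd=float(curves["cum_vpd"].iloc[-1]),
        stress_index=si,
    )
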