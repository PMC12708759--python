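"""Anomaly construction: pointwise linear detrending, deseasonalization,
per-calendar-month variability and seasonal averaging.

All operations are cellwise independent and NaN-aware.  The canonical
anomaly is *detrended + deseasonalized*: the OLS line over the month index
is removed first, then the calendar-month climatology of the detrended
record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .grids import GriddedField

SEASONS = {
    "MAM": (3, 4, 5),
    "FMA": (2, 3, 4),
    "JAS": (7, 8, 9),
    "DJF": (12, 1, 2),
    "DJFM": (12, 1, 2, 3),
}


@dataclass
class AnomalyField(GriddedField):
    """A gridded anomaly with the removed trend/climatology retained.

    ``trend_slope``/``trend_intercept`` are per-cell OLS coefficients on
    the integer month index; ``climatology`` is the 12-month cycle that
    was subtracted (both None when that step was not applied).
    """

    provenance: str = "raw"
    climatology: np.ndarray | None = None
    trend_slope: np.ndarray | None = None
    trend_intercept: np.ndarray | None = None


def _detrend_array(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS-detrend along axis 0, NaN-aware per cell. Returns
    (residuals, slope, intercept)."""
    nt = values.shape[0]
    t = np.arange(nt, dtype=float)
    flat = values.reshape(nt, -1)
    valid = np.isfinite(flat)
    n = valid.sum(axis=0)
    denom = np.maximum(n, 1)
    xm = np.where(valid, t[:, None], 0.0).sum(axis=0) / denom
    ym = np.where(valid, flat, 0.0).sum(axis=0) / denom
    xm = np.where(n > 0, xm, np.nan)
    ym = np.where(n > 0, ym, np.nan)
    dx = np.where(valid, t[:, None] - xm[None, :], 0.0)
    dy = np.where(valid, flat - ym[None, :], 0.0)
    sxx = (dx * dx).sum(axis=0)
    sxy = (dx * dy).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    slope = np.where(n >= 2, slope, np.nan)
    intercept = ym - slope * xm
    resid = flat - (slope[None, :] * t[:, None] + intercept[None, :])
    shp = values.shape
    return (
        resid.reshape(shp),
        slope.reshape(shp[1:]),
        intercept.reshape(shp[1:]),
    )


def _climatology_array(values: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Calendar-month means along axis 0; shape (12, *spatial)."""
    out = np.full((12,) + values.shape[1:], np.nan)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            continue
        sub = values[sel]
        valid = np.isfinite(sub)
        cnt = valid.sum(axis=0)
        s = np.where(valid, sub, 0.0).sum(axis=0)
        out[m - 1] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return out


def remove_linear_trend(field: GriddedField) -> AnomalyField:
    """Subtract the per-cell OLS line (slope and intercept) over time."""
    if len(field.time) < 24:
        raise DataError("detrending requires at least 24 time steps")
    resid, slope, intercept = _detrend_array(field.values)
    return AnomalyField(
        name=field.name,
        units=field.units,
        lat=field.lat,
        lon=field.lon,
        time=field.time,
        values=resid,
        mask=field.mask,
        provenance="detrended",
        trend_slope=slope,
        trend_intercept=intercept,
    )


def monthly_climatology(field: GriddedField) -> np.ndarray:
    """Per-cell calendar-month means, shape (12, nlat, nlon)."""
    if len(field.time) < 12:
        raise DataError("climatology requires at least one full year")
    return _climatology_array(field.values, field.month_of_year)


def deseasonalize(field: GriddedField) -> AnomalyField:
    """Subtract each cell's calendar-month climatology."""
    clim = monthly_climatology(field)
    months = field.month_of_year
    anoms = field.values - clim[months - 1]
    prev = getattr(field, "provenance", "raw")
    prov = "detrended+deseasonalized" if prev == "detrended" else "deseasonalized"
    return AnomalyField(
        name=field.name,
        units=field.units,
        lat=field.lat,
        lon=field.lon,
        time=field.time,
        values=anoms,
        mask=field.mask,
        provenance=prov,
        climatology=clim,
        trend_slope=getattr(field, "trend_slope", None),
        trend_intercept=getattr(field, "trend_intercept", None),
    )


def _joint_anomaly_array(
    values: np.ndarray,
    months: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Remove the OLS trend and the monthly climatology jointly.

    A single detrend->deseasonalize pass leaves a small cross-talk
    residual (the month-index trend fit picks up part of any seasonal
    cycle and vice versa), so the two removals are alternated until both
    increments vanish; the result is the exact projection that
    annihilates trend + cycle.  Returns (anomalies, slope, intercept,
    climatology) with the removed pieces accumulated.
    """
    x = values.copy()
    nt = x.shape[0]
    t = np.arange(nt, dtype=float)
    scale = np.nanmax(np.abs(values)) if np.isfinite(values).any() else 1.0
    scale = scale if scale > 0 else 1.0
    slope_tot = np.zeros(x.shape[1:])
    int_tot = np.zeros(x.shape[1:])
    clim_tot = np.zeros((12,) + x.shape[1:])
    for _ in range(max_iter):
        resid, slope, intercept = _detrend_array(x)
        clim = _climatology_array(resid, months)
        x = resid - np.nan_to_num(clim[months - 1], nan=0.0)
        x = np.where(np.isfinite(resid), x, np.nan)
        slope_tot += np.nan_to_num(slope)
        int_tot += np.nan_to_num(intercept)
        clim_tot += np.nan_to_num(clim)
        step = np.nanmax(
            [np.max(np.abs(np.nan_to_num(slope))) * nt,
             np.max(np.abs(np.nan_to_num(clim)))]
        )
        if step <= tol * scale:
            break
    # cells that never had a valid fit stay missing
    slope_tot = np.where(np.isfinite(values).sum(axis=0) >= 2, slope_tot, np.nan)
    return x, slope_tot, int_tot, clim_tot


def detrended_anomalies(field: GriddedField) -> AnomalyField:
    """Detrended + deseasonalized anomalies — the canonical pipeline.

    Trend and climatology removal are alternated to convergence so that a
    pure trend + seasonal-cycle field maps to exactly zero and the
    residual carries no re-fittable linear trend.
    """
    if len(field.time) < 24:
        raise DataError("detrending requires at least 24 time steps")
    anoms, slope, intercept, clim = _joint_anomaly_array(
        field.values, field.month_of_year
    )
    return AnomalyField(
        name=field.name,
        units=field.units,
        lat=field.lat,
        lon=field.lon,
        time=field.time,
        values=anoms,
        mask=field.mask,
        provenance="detrended+deseasonalized",
        climatology=clim,
        trend_slope=slope,
        trend_intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Series-level counterparts (1-D pandas Series on a monthly DatetimeIndex)


def detrend_series(series: pd.Series) -> pd.Series:
    resid, _, _ = _detrend_array(series.to_numpy(dtype=float)[:, None])
    return pd.Series(resid[:, 0], index=series.index, name=series.name)


def deseasonalize_series(series: pd.Series) -> pd.Series:
    months = pd.DatetimeIndex(series.index).month.to_numpy()
    vals = series.to_numpy(dtype=float)
    clim = _climatology_array(vals[:, None], months)[:, 0]
    return pd.Series(vals - clim[months - 1], index=series.index, name=series.name)


def anomaly_series(series: pd.Series) -> pd.Series:
    """Detrended + deseasonalized series anomaly (joint removal)."""
    months = pd.DatetimeIndex(series.index).month.to_numpy()
    anoms, _, _, _ = _joint_anomaly_array(
        series.to_numpy(dtype=float)[:, None], months
    )
    return pd.Series(anoms[:, 0], index=series.index, name=series.name)


def monthly_std(anoms, months: np.ndarray | None = None) -> np.ndarray:
    """Per-calendar-month sample std (ddof=1); months with < 2 samples NaN.

    ``anoms`` may be an (Anomaly)Field, a pandas Series on a monthly index,
    or a plain array (then ``months`` gives calendar months 1..12).
    """
    if isinstance(anoms, GriddedField):
        vals, months = anoms.values, anoms.month_of_year
    elif isinstance(anoms, pd.Series):
        vals = anoms.to_numpy(dtype=float)
        months = pd.DatetimeIndex(anoms.index).month.to_numpy()
    else:
        vals = np.asarray(anoms, dtype=float)
        if months is None:
            raise ConfigError("months required for plain-array input")
    out = np.full((12,) + vals.shape[1:], np.nan)
    for m in range(1, 13):
        sub = vals[months == m]
        if sub.shape[0] < 2:
            continue
        valid = np.isfinite(sub)
        cnt = valid.sum(axis=0)
        safe = np.maximum(cnt, 1)
        mean = np.where(valid, sub, 0.0).sum(axis=0) / safe
        ss = (np.where(valid, sub - mean, 0.0) ** 2).sum(axis=0)
        out[m - 1] = np.where(cnt >= 2, np.sqrt(ss / np.maximum(cnt - 1, 1)), np.nan)
    return out


def pooled_std(anoms) -> float:
    """Sample std (ddof=1) of a series pooling all calendar months."""
    vals = anoms.to_numpy(dtype=float) if isinstance(anoms, pd.Series) else np.asarray(anoms, float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise DataError("need at least 2 valid points for a std")
    return float(np.std(vals, ddof=1))


def seasonal_mean(series: pd.Series, months) -> pd.Series:
    """Mean over the given calendar months per year; one value per year.

    Seasons spanning the year boundary (containing December and January)
    are assigned to the January year; a year missing any requested month
    is NaN.
    """
    if isinstance(months, str):
        name = months.upper()
        if name not in SEASONS:
            raise ConfigError(f"unknown season name {months!r}")
        months = SEASONS[name]
    months = sorted(set(int(m) for m in months))
    if not months:
        raise ConfigError("empty month set")
    if any(m < 1 or m > 12 for m in months):
        raise ConfigError("months must be in 1..12")
    idx = pd.DatetimeIndex(series.index)
    cal_months = idx.month.to_numpy()
    years = idx.year.to_numpy()
    spans_boundary = 12 in months and 1 in months
    # December (and any trailing months) count toward the following January's year
    season_year = years.copy()
    if spans_boundary:
        late = [m for m in months if m >= 7]
        season_year = np.where(np.isin(cal_months, late), years + 1, years)
    sel = np.isin(cal_months, months)
    vals = series.to_numpy(dtype=float)
    out_years = np.unique(season_year[sel])
    out = []
    for y in out_years:
        pick = sel & (season_year == y)
        got = cal_months[pick]
        if set(got.tolist()) != set(months):
            out.append(np.nan)
        else:
            out.append(float(np.mean(vals[pick])))
    return pd.Series(out, index=pd.Index(out_years, name="year"), name=series.name)
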