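"""Climate-index construction and correlation significance.

Implements the basin-difference multidecadal SST index (North Atlantic
box minus the 60S-60N global band, annually averaged then 11-year
smoothed), an equatorial-Pacific index with its 3-month running mean and
+/-0.5 degC warm/cold classification, sliding-window Pearson
correlations and the Student-t critical correlation value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anomalies import seasonal_mean  # noqa: F401  (re-exported convenience)
from .errors import ConfigError, DataError
from .grids import GriddedField, area_mean, get_region

ENSO_THRESHOLD_C = 0.5


@dataclass
class IndexSeries:
    name: str
    values: pd.Series
    window: int | None = None
    flags: pd.Series | None = None  # warm/cold/neutral classification


@dataclass
class SlidingCorrelation:
    centers: np.ndarray
    r: np.ndarray
    window_years: int
    dof: int
    r_crit: float
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.abs(self.r) > self.r_crit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"center": self.centers, "r": self.r, "significant": self.significant}
        )


def critical_r(dof: int, alpha: float = 0.05, two_tailed: bool = True) -> float:
    """Critical Pearson correlation, r* = t*/sqrt(t*^2 + dof)."""
    if dof < 1:
        raise ConfigError("dof must be >= 1")
    if not 0 < alpha <= 1:
        raise ConfigError("alpha must be in (0, 1]")
    q = 1 - alpha / 2 if two_tailed else 1 - alpha
    tstar = stats.t.ppf(q, dof)
    return float(tstar / np.sqrt(tstar**2 + dof))


def amv_index(sst_anoms: GriddedField, smooth_years: int = 11) -> IndexSeries:
    """North Atlantic box SSTA minus 60S-60N global-band SSTA.

    Monthly difference -> calendar-year means -> centered ``smooth_years``
    running mean (endpoints missing).
    """
    na = area_mean(sst_anoms, get_region("amv_north_atlantic"))
    glob = area_mean(sst_anoms, get_region("global_band"))
    monthly = na - glob
    annual = monthly.groupby(pd.DatetimeIndex(monthly.index).year).mean()
    annual.index.name = "year"
    if smooth_years % 2 != 1:
        raise ConfigError("smoothing window must be odd")
    sm = annual.rolling(smooth_years, center=True, min_periods=smooth_years).mean()
    return IndexSeries(name="amv", values=sm, window=smooth_years)


def nino34_oni(sst_anoms: GriddedField) -> IndexSeries:
    """Area-mean SSTA in the equatorial-Pacific box, 3-month running mean.

    Months beyond +/-0.5 degC are flagged warm/cold, else neutral.
    """
    box = area_mean(sst_anoms, get_region("nino34"))
    oni = box.rolling(3, center=True, min_periods=3).mean()
    oni.name = "oni"
    flags = pd.Series("neutral", index=oni.index)
    flags[oni > ENSO_THRESHOLD_C] = "warm"
    flags[oni < -ENSO_THRESHOLD_C] = "cold"
    flags[oni.isna()] = ""
    return IndexSeries(name="oni", values=oni, window=3, flags=flags)


def sliding_pearson(
    x: pd.Series,
    y: pd.Series,
    window_years: int = 21,
    alpha: float = 0.05,
    dof: int | None = None,
) -> SlidingCorrelation:
    """Pearson r in centered sliding windows over aligned annual series.

    ``dof`` defaults to ``window_years - 1`` (the convention that yields
    the printed 0.42 threshold for 21-year windows at 95%); pass
    ``window_years - 2`` for the textbook choice.
    """
    if not x.index.equals(y.index):
        x, y = x.align(y, join="inner")
    n = len(x)
    if n < window_years:
        raise DataError("series shorter than the correlation window")
    if window_years % 2 != 1:
        raise ConfigError("window_years must be odd (centered windows)")
    if dof is None:
        dof = window_years - 1
    half = window_years // 2
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    centers = x.index.to_numpy()[half : n - half]
    rs = np.full(len(centers), np.nan)
    for i in range(len(centers)):
        xs = xv[i : i + window_years]
        ys = yv[i : i + window_years]
        ok = np.isfinite(xs) & np.isfinite(ys)
        if ok.sum() < 3:
            continue
        if np.std(xs[ok]) == 0 or np.std(ys[ok]) == 0:
            continue
        rs[i] = np.corrcoef(xs[ok], ys[ok])[0, 1]
    return SlidingCorrelation(
        centers=centers,
        r=rs,
        window_years=window_years,
        dof=dof,
        r_crit=critical_r(dof, alpha),
        alpha=alpha,
    )


def compare_series(a: pd.Series, b: pd.Series) -> dict[str, float]:
    """Bias, RMSE and Pearson r of two aligned series (pairwise-complete)."""
    if not a.index.equals(b.index):
        a, b = a.align(b, join="inner")
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    ok = np.isfinite(av) & np.isfinite(bv)
    if ok.sum() < 2:
        raise DataError("need at least 2 valid pairs")
    d = av[ok] - bv[ok]
    return {
        "bias": float(np.mean(d)),
        "rmse": float(np.sqrt(np.mean(d**2))),
        "pearson_r": float(np.corrcoef(av[ok], bv[ok])[0, 1]),
    }
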