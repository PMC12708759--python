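"""Coastal Hovmoeller diagrams and temporal filtering for propagating
sea-level signals.

The decadal band is removed with a brick-wall FFT high-pass (cutoff
period 10 years by default; the coefficient exactly at the cutoff is
kept in the passband), subseasonal noise with a 1-2-1 running weighted
average.  Propagation speed is diagnosed from the lag of maximum
cross-correlation between two path positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, GapError
from .grids import CoastalPath, GriddedField, extract_along_path

MONTHS_PER_YEAR = 12


@dataclass
class Hovmoeller:
    """[time, position] anomaly diagram along a coastal/equatorial path."""

    positions: np.ndarray  # along-path coordinate, degrees
    time: np.ndarray
    values: np.ndarray  # (time, position)
    path_name: str = "path"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.time), len(self.positions)):
            raise ConfigError("values shape must be (time, position)")
        d = np.diff(self.positions)
        if len(d) and not np.all(d > 0):
            raise ConfigError("positions must be strictly increasing")

    def column(self, position: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.positions - position)))
        return self.values[:, k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.DatetimeIndex(self.time),
            columns=[f"{p:g}" for p in self.positions],
        )


def build_hovmoeller(
    field: GriddedField, path: CoastalPath, band_width: float = 1.0
) -> Hovmoeller:
    """Band-averaged anomalies along a path, ordered by path label."""
    vals = extract_along_path(field, path, band_width)
    return Hovmoeller(
        positions=path.labels, time=field.time, values=vals, path_name=path.name
    )


def _apply_columns(x, fn):
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return fn(arr)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = fn(arr[:, j])
    return out


def highpass_fft(x, cutoff_period_years: float = 10.0) -> np.ndarray:
    """Brick-wall FFT high-pass on monthly data.

    Zeroes every Fourier coefficient with period longer than the cutoff,
    including the mean; the coefficient exactly at the cutoff period is
    retained.  Input must be gapless.
    """
    if cutoff_period_years <= 0:
        raise ConfigError("cutoff period must be positive")
    cutoff_freq = 1.0 / (cutoff_period_years * MONTHS_PER_YEAR)  # cycles/month

    def one(col: np.ndarray) -> np.ndarray:
        if np.isnan(col).any():
            raise GapError("high-pass filter requires a gapless series")
        n = len(col)
        spec = np.fft.rfft(col - col.mean())
        freqs = np.fft.rfftfreq(n, d=1.0)
        spec[freqs < cutoff_freq - 1e-12] = 0.0
        return np.fft.irfft(spec, n=n)

    return _apply_columns(x, one)


def smooth_121(x) -> np.ndarray:
    """1-2-1 running weighted average; renormalized 2-point endpoints."""

    def one(col: np.ndarray) -> np.ndarray:
        n = len(col)
        if n < 3:
            raise ConfigError("1-2-1 smoothing needs at least 3 points")
        out = np.empty(n)
        out[1:-1] = 0.25 * col[:-2] + 0.5 * col[1:-1] + 0.25 * col[2:]
        out[0] = (2.0 * col[0] + col[1]) / 3.0
        out[-1] = (col[-2] + 2.0 * col[-1]) / 3.0
        return out

    return _apply_columns(x, one)


def filter_hovmoeller(
    hov: Hovmoeller, cutoff_period_years: float = 10.0, smooth: bool = True
) -> Hovmoeller:
    """High-pass then 1-2-1 smooth every column (caption order)."""
    vals = highpass_fft(hov.values, cutoff_period_years)
    if smooth:
        vals = smooth_121(vals)
    return Hovmoeller(
        positions=hov.positions,
        time=hov.time,
        values=vals,
        path_name=hov.path_name,
    )


def propagation_lag(
    hov: Hovmoeller, pos_a: float, pos_b: float, max_lag: int = 12
) -> tuple[int, float]:
    """Lag (months) maximizing cross-correlation of column b against a.

    Positive lag means the signal at ``pos_b`` follows ``pos_a``.
    """
    if max_lag < 1:
        raise ConfigError("max_lag must be >= 1")
    a = hov.column(pos_a)
    b = hov.column(pos_b)
    n = len(a)
    if n < 3 * max_lag:
        raise DataError("series overlap too short for the requested max_lag")
    best_lag, best_r = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        if r > best_r:
            best_lag, best_r = lag, r
    if not np.isfinite(best_r):
        raise DataError("no valid overlap between the two columns")
    return best_lag, best_r
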