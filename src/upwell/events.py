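"""Extreme-event detection on region-mean anomaly series.

An extreme event is a maximal run of consecutive months whose anomaly
stays strictly beyond ``k`` pooled standard deviations of the series
(same sign throughout), lasting at least ``min_duration`` months.  The
peak is the month of largest absolute anomaly within the run (ties break
toward the earlier month).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .anomalies import SEASONS, pooled_std
from .errors import ConfigError, DegenerateSeriesError


@dataclass(frozen=True)
class Event:
    sign: str  # "high" | "low"
    start: int  # month index into the series
    end: int  # inclusive
    peak: int
    peak_value: float

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


@dataclass
class EventSet:
    """Detected events plus the threshold bookkeeping that produced them."""

    events: list[Event] = dc_field(default_factory=list)
    sigma: float = float("nan")
    threshold: float = float("nan")
    k: float = float("nan")
    min_duration: int = 2
    index: pd.DatetimeIndex | None = None  # time axis of the source series

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def peaks(self) -> list[int]:
        return [e.peak for e in self.events]

    def peak_months(self) -> list[int]:
        """Calendar month (1..12) of each event peak."""
        if self.index is None:
            raise ConfigError("EventSet has no time index")
        return [int(self.index[e.peak].month) for e in self.events]

    def peak_years(self) -> list[int]:
        if self.index is None:
            raise ConfigError("EventSet has no time index")
        return [int(self.index[e.peak].year) for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            row = {
                "sign": e.sign,
                "start": e.start,
                "end": e.end,
                "peak": e.peak,
                "duration": e.duration,
                "peak_value": e.peak_value,
                "sigma": self.sigma,
                "threshold": self.threshold,
            }
            if self.index is not None:
                row["peak_date"] = self.index[e.peak].strftime("%Y-%m")
            rows.append(row)
        cols = ["sign", "start", "end", "peak", "duration", "peak_value", "sigma", "threshold"]
        if self.index is not None:
            cols.append("peak_date")
        return pd.DataFrame(rows, columns=cols)


def detect_extreme_events(
    series: pd.Series | np.ndarray,
    k: float = 0.8,
    min_duration: int = 2,
) -> EventSet:
    """Detect threshold exceedance runs in an anomaly series.

    The threshold is ``k`` times the pooled sample standard deviation of
    the full series (all calendar months).  Exceedance is strict
    (|anomaly| > threshold).
    """
    if min_duration < 1:
        raise ConfigError("min_duration must be >= 1")
    if isinstance(series, pd.Series):
        index = pd.DatetimeIndex(series.index)
        vals = series.to_numpy(dtype=float)
    else:
        index = None
        vals = np.asarray(series, dtype=float)
    sigma = pooled_std(vals)
    if sigma == 0:
        raise DegenerateSeriesError("series has zero variance")
    thr = k * sigma
    state = np.zeros(len(vals), dtype=int)
    state[vals > thr] = 1
    state[vals < -thr] = -1
    state[~np.isfinite(vals)] = 0

    events: list[Event] = []
    i = 0
    n = len(vals)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        if j - i + 1 >= min_duration:
            seg = np.abs(vals[i : j + 1])
            peak = i + int(np.argmax(seg))  # argmax ties -> earliest
            events.append(
                Event(
                    sign="high" if state[i] > 0 else "low",
                    start=i,
                    end=j,
                    peak=peak,
                    peak_value=float(vals[peak]),
                )
            )
        i = j + 1
    return EventSet(
        events=events,
        sigma=sigma,
        threshold=thr,
        k=k,
        min_duration=min_duration,
        index=index,
    )


def filter_by_peak_season(events: EventSet, season=(3, 4, 5)) -> EventSet:
    """Keep only events whose *peak* falls in the given calendar months."""
    if isinstance(season, str):
        name = season.upper()
        if name not in SEASONS:
            raise ConfigError(f"unknown season name {season!r}")
        season = SEASONS[name]
    season = set(int(m) for m in season)
    if events.index is None:
        raise ConfigError("events need a time index for season filtering")
    kept = [
        e for e in events.events if int(events.index[e.peak].month) in season
    ]
    return EventSet(
        events=kept,
        sigma=events.sigma,
        threshold=events.threshold,
        k=events.k,
        min_duration=events.min_duration,
        index=events.index,
    )


def event_summary(events: EventSet) -> pd.DataFrame:
    """One row per event: sign, peak year/month, duration, amplitude."""
    df = events.to_frame()
    if events.index is not None and len(df):
        df["peak_year"] = [events.index[e.peak].year for e in events.events]
        df["peak_month"] = [events.index[e.peak].month for e in events.events]
    return df
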