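"""Lag composites keyed to event peaks and their bootstrap significance.

The null distribution is built by resampling *without replacement*:
each of ``n_resamples`` artificial composites averages ``n_events``
distinct months drawn uniformly from the valid record.  A composite
value is significant at level ``alpha`` iff it falls outside the
``[alpha/2, 1 - alpha/2]`` percentile range (type-7 / linear
interpolation) of the sorted artificial averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .grids import GriddedField


def _as_time_first_array(data) -> np.ndarray:
    if isinstance(data, GriddedField):
        return data.values
    if isinstance(data, pd.Series):
        return data.to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


@dataclass
class CompositeResult:
    """Per-lag composite means with optional bootstrap masks.

    ``mean`` has shape ``(n_lags, *spatial)`` (``(n_lags,)`` for series);
    ``counts`` tracks how many events contributed at each lag.
    """

    lags: np.ndarray
    mean: np.ndarray
    n_events: int
    counts: np.ndarray
    sig_mask: np.ndarray | None = None
    lower: np.ndarray | None = None  # 2.5th percentile of the null
    upper: np.ndarray | None = None  # 97.5th percentile
    alpha: float | None = None
    n_resamples: int | None = None
    seed: int | None = None
    meta: dict = dc_field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Series composites as a tidy table (scalar per lag)."""
        if self.mean.ndim != 1:
            raise ConfigError("to_frame only applies to series composites")
        df = pd.DataFrame({"lag": self.lags, "mean": self.mean, "n": self.counts})
        if self.sig_mask is not None:
            df["significant"] = self.sig_mask
            df["lower"] = np.broadcast_to(self.lower, self.mean.shape)
            df["upper"] = np.broadcast_to(self.upper, self.mean.shape)
        return df


def composite_at_lags(data, peaks, lags=range(-3, 4)) -> CompositeResult:
    """Mean across events of the anomaly at (peak + lag), per lag.

    Events whose (peak + lag) falls outside the record are dropped at
    that lag only; the per-lag usable count is recorded.
    """
    vals = _as_time_first_array(data)
    nt = vals.shape[0]
    peaks = np.asarray(list(peaks), dtype=int)
    if peaks.size == 0:
        raise DataError("no events to composite")
    if np.any((peaks < 0) | (peaks >= nt)):
        raise DataError("event peak outside the record")
    lags = np.asarray(list(lags), dtype=int)
    mean = np.full((len(lags),) + vals.shape[1:], np.nan)
    counts = np.zeros(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        idx = peaks + lag
        idx = idx[(idx >= 0) & (idx < nt)]
        counts[i] = len(idx)
        if len(idx):
            with np.errstate(invalid="ignore"):
                mean[i] = np.nanmean(vals[idx], axis=0)
    return CompositeResult(lags=lags, mean=mean, n_events=len(peaks), counts=counts)


def bootstrap_null(
    data,
    n_events: int,
    n_resamples: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Artificial composite averages of ``n_events`` distinct months.

    Returns an array of shape ``(n_resamples, *spatial)``.
    """
    vals = _as_time_first_array(data)
    if vals.ndim == 1:
        valid = np.isfinite(vals)
    else:
        valid = np.isfinite(vals).any(axis=tuple(range(1, vals.ndim)))
    pool = np.nonzero(valid)[0]
    if n_events > pool.size:
        raise DataError(
            f"cannot draw {n_events} distinct months from {pool.size} valid ones"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    # vectorized sampling without replacement: rank random keys per row
    keys = rng.random((n_resamples, pool.size))
    take = np.argpartition(keys, n_events - 1, axis=1)[:, :n_events]
    months = pool[take]  # (n_resamples, n_events)
    with np.errstate(invalid="ignore"):
        null = np.nanmean(vals[months], axis=1)
    return null


def bootstrap_significance(
    data,
    composite: CompositeResult,
    n_resamples: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CompositeResult:
    """Attach percentile bounds and a significance mask to a composite."""
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    null = bootstrap_null(
        data, composite.n_events, n_resamples=n_resamples, seed=seed
    )
    lower = np.percentile(null, 100 * alpha / 2, axis=0)
    upper = np.percentile(null, 100 * (1 - alpha / 2), axis=0)
    sig = (composite.mean < lower) | (composite.mean > upper)
    sig &= np.isfinite(composite.mean)
    composite.sig_mask = sig
    composite.lower = lower
    composite.upper = upper
    composite.alpha = alpha
    composite.n_resamples = n_resamples
    composite.seed = seed
    return composite
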