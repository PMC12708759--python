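"""Synthetic monthly gridded fields and budget terms with known truth.

Every pipeline stage is exercised against this generator: fields carry a
configurable seasonal cycle (productivity peaking in boreal spring by
default), pointwise linear trends, AR(1) interannual noise, injected
multi-month extreme anomalies over the coastal band (productivity and
temperature in anti-phase), a poleward-propagating coastal sea-level
pulse of fixed phase speed, and budget terms that close exactly by
construction.  The idealized coastline is meridional: land at
``lon >= coast_lon``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import ConfigError
from .grids import GriddedField, Region, month_range, region_mask
from .heat_budget import CP, RHO0, SECONDS_PER_DAY, HeatBudgetTerms

_BURN_IN = 60  # AR(1) spin-up months discarded

#: fixed per-variable sub-stream offsets so regenerating one variable is
#: independent of the others
_STREAM_OFFSET = {
    "npp": 1,
    "sst": 2,
    "taux": 3,
    "tauy": 4,
    "sla": 5,
    "budget": 6,
    "series": 7,
}


@dataclass(frozen=True)
class VariableSpec:
    mean: float = 0.0
    seasonal_amplitude: float = 1.0
    peak_month: int = 4  # calendar month of the climatological maximum
    noise_sd: float = 0.2
    trend_per_year: float = 0.0
    units: str = ""


@dataclass(frozen=True)
class EventSpec:
    """An injected anomaly: half-sine pulse over ``duration`` months.

    ``amplitude`` is in units of the target variable's noise sd; ``sign``
    is +1 (high) or -1 (low) for the productivity field (temperature
    receives the opposite sign).
    """

    start: int
    duration: int
    sign: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ConfigError("event duration must be >= 1")
        if self.sign not in (-1, 1):
            raise ConfigError("event sign must be +1 or -1")

    @property
    def end(self) -> int:
        return self.start + self.duration - 1

    def profile(self) -> np.ndarray:
        i = np.arange(self.duration)
        return np.sin(np.pi * (i + 0.5) / self.duration)

    @property
    def peak(self) -> int:
        return self.start + int(np.argmax(self.profile()))


@dataclass(frozen=True)
class WaveSpec:
    """Poleward-propagating coastal sea-level pulse."""

    speed: float = 5.0  # degrees latitude per month
    amplitude: float = 5.0  # cm
    start_month: int = 12
    start_lat: float = 0.0
    width: float = 1.0  # Gaussian half-width in degrees latitude
    band_width: float = 1.0  # coastal band carrying the signal, deg lon


_DEFAULT_VARIABLES = {
    "npp": VariableSpec(mean=3.0, seasonal_amplitude=1.0, peak_month=4,
                        noise_sd=0.25, units="gC m-2 day-1"),
    "sst": VariableSpec(mean=24.0, seasonal_amplitude=3.0, peak_month=9,
                        noise_sd=0.3, units="degC"),
    "taux": VariableSpec(mean=-0.05, seasonal_amplitude=0.02, peak_month=1,
                         noise_sd=0.01, units="N m-2"),
    "tauy": VariableSpec(mean=0.02, seasonal_amplitude=0.01, peak_month=7,
                         noise_sd=0.01, units="N m-2"),
    "sla": VariableSpec(mean=0.0, seasonal_amplitude=2.0, peak_month=10,
                        noise_sd=1.0, units="cm"),
}


@dataclass
class SyntheticConfig:
    n_years: int = 21
    seed: int = 0
    start: str = "2003-01"
    lat_min: float = -5.0
    lat_max: float = 25.0
    lon_min: float = -15.0
    lon_max: float = 5.0
    spacing: float = 1.0
    coast_lon: float = 0.0
    ar1_phi: float = 0.3
    variables: dict = dc_field(default_factory=lambda: dict(_DEFAULT_VARIABLES))
    events: list = dc_field(default_factory=list)
    wave: WaveSpec | None = None
    event_region: Region = dc_field(
        default_factory=lambda: Region("coastal_band", 9.0, 18.0, band_width=2.0)
    )

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ConfigError("n_years must be >= 3")
        if not abs(self.ar1_phi) < 1:
            raise ConfigError("|ar1_phi| must be < 1")
        self.events = [
            e if isinstance(e, EventSpec) else EventSpec(**e) for e in self.events
        ]
        self.variables = {
            k: (v if isinstance(v, VariableSpec) else VariableSpec(**v))
            for k, v in self.variables.items()
        }
        if isinstance(self.wave, dict):
            self.wave = WaveSpec(**self.wave)
        n_months = self.n_years * 12
        for e in self.events:
            if e.start < 0 or e.end >= n_months:
                raise ConfigError(
                    f"event ({e.start}, duration {e.duration}) extends past "
                    f"the {n_months}-month record"
                )

    @property
    def n_months(self) -> int:
        return self.n_years * 12

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        lat = np.arange(self.lat_min, self.lat_max + 1e-9, self.spacing)
        lon = np.arange(self.lon_min, self.lon_max + 1e-9, self.spacing)
        return lat, lon


@dataclass
class SyntheticTruth:
    """Ground-truth record mirroring the generator arithmetic exactly."""

    events: list[dict] = dc_field(default_factory=list)
    trend_per_year: dict[str, float] = dc_field(default_factory=dict)
    noise_sd: dict[str, float] = dc_field(default_factory=dict)
    climatology: dict[str, list[float]] = dc_field(default_factory=dict)
    wave_speed: float | None = None
    ar1_phi: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM_OFFSET[stream]])


def _ar1(rng: np.random.Generator, phi: float, sd: float, shape: tuple) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal std ``sd``."""
    nt = shape[0]
    eps = rng.standard_normal((nt + _BURN_IN,) + shape[1:])
    eps *= sd * np.sqrt(1.0 - phi**2)
    x = sp_signal.lfilter([1.0], [1.0, -phi], eps, axis=0)
    return x[_BURN_IN:]


def _climatology(spec: VariableSpec) -> np.ndarray:
    m = np.arange(1, 13)
    return spec.mean + spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (m - spec.peak_month) / 12.0
    )


def generate_fields(
    config: SyntheticConfig,
) -> tuple[dict[str, GriddedField], SyntheticTruth]:
    """Generate all gridded variables plus the ground-truth sidecar."""
    lat, lon = config.grid()
    time = month_range(config.start, config.n_months)
    months = pd.DatetimeIndex(time).month.to_numpy()
    t_idx = np.arange(config.n_months, dtype=float)
    mask = np.broadcast_to(lon[None, :] < config.coast_lon, (len(lat), len(lon))).copy()

    truth = SyntheticTruth(ar1_phi=config.ar1_phi, seed=config.seed)
    fields: dict[str, GriddedField] = {}
    ev_mask = None

    for name, spec in config.variables.items():
        clim12 = _climatology(spec)
        base = clim12[months - 1][:, None, None]
        trend = spec.trend_per_year * (t_idx / 12.0)[:, None, None]
        noise = _ar1(
            _rng(config.seed, name), config.ar1_phi, spec.noise_sd,
            (config.n_months, len(lat), len(lon)),
        )
        vals = base + trend + noise
        field = GriddedField(
            name=name, units=spec.units, lat=lat, lon=lon, time=time,
            values=vals, mask=mask,
        )
        fields[name] = field
        truth.trend_per_year[name] = spec.trend_per_year
        truth.noise_sd[name] = spec.noise_sd
        truth.climatology[name] = [float(v) for v in clim12]

    # injected extremes over the coastal event region: productivity gets the
    # configured sign, temperature the opposite (anti-phase)
    if config.events:
        ev_mask = region_mask(fields["npp"], config.event_region)
        for e in config.events:
            prof = e.profile()
            for var, sgn in (("npp", e.sign), ("sst", -e.sign)):
                if var not in fields:
                    continue
                amp = e.amplitude * config.variables[var].noise_sd
                pulse = sgn * amp * prof
                fields[var].values[e.start : e.end + 1][:, ev_mask] += pulse[:, None]
            truth.events.append(
                {
                    "variable": "npp",
                    "sign": "high" if e.sign > 0 else "low",
                    "start": e.start,
                    "end": e.end,
                    "peak": e.peak,
                    "amplitude_sigma": e.amplitude,
                }
            )

    if config.wave is not None and "sla" in fields:
        w = config.wave
        band = np.zeros_like(mask)
        for i in range(len(lat)):
            sel = (lon < config.coast_lon) & (lon >= config.coast_lon - w.band_width)
            band[i] = sel & mask[i]
        for t in range(w.start_month, config.n_months):
            center = w.start_lat + w.speed * (t - w.start_month)
            if center > config.lat_max + 4 * w.width:
                break
            bump = w.amplitude * np.exp(-((lat - center) ** 2) / (2.0 * w.width**2))
            fields["sla"].values[t][band] += np.broadcast_to(
                bump[:, None], band.shape
            )[band]
        truth.wave_speed = w.speed

    return fields, truth


@dataclass
class BudgetData:
    terms: HeatBudgetTerms
    q: pd.Series  # total absorbed surface flux, W m-2
    h: pd.Series  # mixed-layer depth, m


_BUDGET_TERMS = {
    # name: (mean degC/day, seasonal amplitude, peak month, noise sd)
    "xadv": (-0.01, 0.01, 4, 0.005),
    "yadv": (0.0, 0.005, 7, 0.004),
    "zadv": (-0.005, 0.005, 5, 0.003),
    "ldf": (0.01, 0.005, 4, 0.004),
    "zdf": (-0.03, 0.01, 4, 0.006),
    "qnet": (0.04, 0.03, 4, 0.01),
}


def generate_budget(
    config: SyntheticConfig,
    h_mean: float = 30.0,
    h_seasonal: float = 10.0,
    h_noise_sd: float = 2.0,
    term_specs: dict | None = None,
) -> tuple[BudgetData, SyntheticTruth]:
    """Budget term series closing exactly: tot = sum of the six terms.

    The flux/depth pair is emitted consistently with the storage term:
    Q = qnet * rho0 * cp * H / 86400, so recomputing the storage from
    (Q, H) reproduces ``qnet`` to machine precision.
    """
    specs = dict(_BUDGET_TERMS)
    if term_specs:
        specs.update(term_specs)
    time = month_range(config.start, config.n_months)
    months = pd.DatetimeIndex(time).month.to_numpy()
    rng = _rng(config.seed, "budget")

    series = {}
    truth = SyntheticTruth(ar1_phi=config.ar1_phi, seed=config.seed)
    for name, (mean, amp, peak, sd) in specs.items():
        clim = mean + amp * np.cos(2 * np.pi * (np.arange(1, 13) - peak) / 12.0)
        noise = _ar1(rng, config.ar1_phi, sd, (config.n_months,))
        series[name] = pd.Series(
            clim[months - 1] + noise, index=pd.DatetimeIndex(time), name=name
        )
        truth.noise_sd[name] = sd
        truth.climatology[name] = [float(v) for v in clim]

    h_clim = h_mean + h_seasonal * np.cos(2 * np.pi * (np.arange(1, 13) - 8) / 12.0)
    h_vals = h_clim[months - 1] + _ar1(rng, config.ar1_phi, h_noise_sd, (config.n_months,))
    if np.any(h_vals <= 0):
        raise ConfigError("mixed-layer depth became non-positive; reduce h_noise_sd")
    h = pd.Series(h_vals, index=pd.DatetimeIndex(time), name="h")
    q = series["qnet"] / SECONDS_PER_DAY * RHO0 * CP * h
    q.name = "q"

    tot = sum(series.values())
    tot.name = "tot"
    terms = HeatBudgetTerms(tot=tot, **series)
    return BudgetData(terms=terms, q=q, h=h), truth


def make_event_series(
    n_months: int,
    events: list[tuple[int, int, int, float]],
    noise_sd: float = 0.1,
    ar1_phi: float = 0.3,
    seed: int = 0,
    start: str = "2003-01",
) -> tuple[pd.Series, list[dict]]:
    """A 1-D anomaly series with absolute-amplitude half-sine events.

    ``events`` entries are (start, duration, sign, amplitude) with the
    amplitude in the series' own units.  Returns the series and truth
    records (start/end/peak/sign).
    """
    time = month_range(start, n_months)
    vals = _ar1(_rng(seed, "series"), ar1_phi, noise_sd, (n_months,))
    truth = []
    for st, dur, sgn, amp in events:
        e = EventSpec(start=st, duration=dur, sign=sgn, amplitude=1.0)
        if e.end >= n_months:
            raise ConfigError("event extends past the record")
        vals[st : e.end + 1] += sgn * amp * e.profile()
        truth.append(
            {"start": st, "end": e.end, "peak": e.peak,
             "sign": "high" if sgn > 0 else "low", "amplitude": amp}
        )
    return pd.Series(vals, index=pd.DatetimeIndex(time), name="anomaly"), truth
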