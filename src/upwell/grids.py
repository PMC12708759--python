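"""Gridded monthly fields, regions, coastal paths and spatial reductions.

The :class:`GriddedField` is the common currency of the pipeline: a monthly
``[time, lat, lon]`` array with an ocean mask, serialized as CF-style
NetCDF.  Regions are either lat/lon boxes or coastal bands (a strip of
ocean cells within a fixed longitude offset west of the coastline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    AlignmentError,
    AxisError,
    ConfigError,
    EmptyRegionError,
    FormatError,
)

EARTH_RADIUS_M = 6_371_000.0


def month_range(start: str, n_months: int) -> np.ndarray:
    """Contiguous monthly time axis (month starts) as datetime64[ns]."""
    return pd.date_range(start, periods=n_months, freq="MS").to_numpy()


def _check_monthly(time: np.ndarray) -> None:
    t = pd.DatetimeIndex(time)
    if len(t) == 0:
        raise AxisError("empty time axis")
    periods = t.to_period("M")
    steps = np.diff(periods.asi8)
    if len(steps) and not np.all(steps == 1):
        raise AxisError("time axis is not contiguous monthly")


@dataclass
class GriddedField:
    """A monthly lat x lon x time gridded variable with an ocean mask.

    ``values`` has shape ``(time, lat, lon)`` with NaN at missing cells;
    ``mask`` is ``(lat, lon)`` boolean, True on valid ocean cells.
    """

    name: str
    units: str
    lat: np.ndarray
    lon: np.ndarray
    time: np.ndarray
    values: np.ndarray
    mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        _check_monthly(self.time)
        for vec, label in ((self.lat, "lat"), (self.lon, "lon")):
            d = np.diff(vec)
            if len(d) and not (np.all(d > 0) or np.all(d < 0)):
                raise AxisError(f"{label} axis not strictly monotonic")
        if self.values.shape != (len(self.time), len(self.lat), len(self.lon)):
            raise AxisError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.time)}, {len(self.lat)}, {len(self.lon)})"
            )
        if self.mask is None:
            self.mask = ~np.all(np.isnan(self.values), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        # masked-out cells are missing everywhere
        self.values = np.where(self.mask[None, :, :], self.values, np.nan)

    @property
    def month_of_year(self) -> np.ndarray:
        """Calendar month (1..12) of each time step."""
        return pd.DatetimeIndex(self.time).month.to_numpy()

    @property
    def year(self) -> np.ndarray:
        return pd.DatetimeIndex(self.time).year.to_numpy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy_with(self, **kwargs) -> "GriddedField":
        out = replace(self, **kwargs)
        return out

    def to_xarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            name=self.name,
            attrs={"units": self.units},
        )
        return da


def write_field(field: GriddedField, path) -> None:
    """Write a field as CF-style NetCDF (classic format, scipy backend)."""
    da = field.to_xarray()
    ds = da.to_dataset()
    ds["ocean_mask"] = xr.DataArray(
        field.mask.astype(np.int8), dims=("lat", "lon")
    )
    ds.lat.attrs["units"] = "degrees_north"
    ds.lon.attrs["units"] = "degrees_east"
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_field(path, variable: str) -> GriddedField:
    """Read one ``[time, lat, lon]`` variable from a NetCDF file.

    The mask is taken from an ``ocean_mask`` variable when present,
    otherwise inferred from cells missing at every time step.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds:
            raise FormatError(f"variable {variable!r} not found in {path}")
        da = ds[variable]
        if set(da.dims) != {"time", "lat", "lon"}:
            raise FormatError(
                f"variable {variable!r} must have (time, lat, lon) dims, "
                f"got {da.dims}"
            )
        da = da.transpose("time", "lat", "lon")
        mask = None
        if "ocean_mask" in ds:
            mask = ds["ocean_mask"].values.astype(bool)
        return GriddedField(
            name=variable,
            units=str(da.attrs.get("units", "")),
            lat=ds["lat"].values,
            lon=ds["lon"].values,
            time=ds["time"].values,
            values=da.values,
            mask=mask,
        )


# ---------------------------------------------------------------------------
# Regions


@dataclass(frozen=True)
class Region:
    """A lat/lon box or a coastal band of fixed longitudinal width."""

    kind: str  # "latlon_box" | "coastal_band"
    lat_min: float
    lat_max: float
    lon_min: float = -180.0
    lon_max: float = 180.0
    band_width: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("latlon_box", "coastal_band"):
            raise ConfigError(f"unknown region kind {self.kind!r}")
        if not self.lat_min < self.lat_max:
            raise ConfigError("lat_min must be < lat_max")
        if self.kind == "coastal_band" and not self.band_width > 0:
            raise ConfigError("coastal band requires band_width > 0")


#: Built-in named regions used throughout the pipeline.
REGION_REGISTRY: dict[str, Region] = {
    "CDNI": Region("coastal_band", 9.0, 18.0, band_width=2.0, name="CDNI"),
    "nino34": Region("latlon_box", -5.0, 5.0, -170.0, -120.0, name="nino34"),
    "amv_north_atlantic": Region(
        "latlon_box", 0.0, 60.0, -80.0, 0.0, name="amv_north_atlantic"
    ),
    "global_band": Region(
        "latlon_box", -60.0, 60.0, -180.0, 180.0, name="global_band"
    ),
}


def get_region(name: str) -> Region:
    try:
        return REGION_REGISTRY[name]
    except KeyError:
        raise ConfigError(f"unknown region {name!r}") from None


def _coastal_band_mask(field: GriddedField, region: Region) -> np.ndarray:
    """Ocean cells within ``band_width`` degrees of longitude west of the
    nearest coastline (land) cell at the same latitude."""
    ocean = field.mask
    land = ~ocean
    nlat, nlon = ocean.shape
    out = np.zeros_like(ocean)
    in_lat = (field.lat >= region.lat_min) & (field.lat <= region.lat_max)
    for i in np.nonzero(in_lat)[0]:
        land_lons = field.lon[land[i]]
        if land_lons.size == 0:
            continue
        for j in range(nlon):
            if not ocean[i, j]:
                continue
            east = land_lons[land_lons > field.lon[j]]
            if east.size == 0:
                continue
            if east.min() - field.lon[j] <= region.band_width:
                out[i, j] = True
    return out


def region_mask(field: GriddedField, region: Region) -> np.ndarray:
    """Boolean (lat, lon) mask of ocean cells belonging to ``region``."""
    if region.kind == "latlon_box":
        inlat = (field.lat >= region.lat_min) & (field.lat <= region.lat_max)
        inlon = (field.lon >= region.lon_min) & (field.lon <= region.lon_max)
        sel = inlat[:, None] & inlon[None, :] & field.mask
    else:
        sel = _coastal_band_mask(field, region)
    if not sel.any():
        raise EmptyRegionError(
            f"region {region.name or region.kind} selects no ocean cells"
        )
    return sel


def area_mean(field: GriddedField, region: Region | np.ndarray) -> pd.Series:
    """cos(latitude)-weighted spatial mean over a region, per time step.

    Missing cells are excluded per time step; a step where every selected
    cell is missing yields NaN.
    """
    sel = region if isinstance(region, np.ndarray) else region_mask(field, region)
    if not sel.any():
        raise EmptyRegionError("empty region mask")
    w2d = np.cos(np.deg2rad(field.lat))[:, None] * np.ones_like(field.lon)[None, :]
    w2d = np.where(sel, w2d, 0.0)
    vals = field.values
    valid = np.isfinite(vals) & sel[None, :, :]
    w3d = np.where(valid, w2d[None, :, :], 0.0)
    wsum = w3d.sum(axis=(1, 2))
    num = np.nansum(np.where(valid, vals, 0.0) * w3d, axis=(1, 2))
    with np.errstate(invalid="ignore"):
        out = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), np.nan)
    return pd.Series(out, index=pd.DatetimeIndex(field.time), name=field.name)


def wind_stress_curl(taux: GriddedField, tauy: GriddedField) -> GriddedField:
    """curl(tau) = d(tauy)/dx - d(taux)/dy on the sphere, N m^-3.

    Centered differences in the interior, one-sided at edges; derivatives
    touching missing cells come out missing (NaN propagation).
    """
    if (
        taux.values.shape != tauy.values.shape
        or not np.array_equal(taux.lat, tauy.lat)
        or not np.array_equal(taux.lon, tauy.lon)
        or not np.array_equal(taux.time, tauy.time)
    ):
        raise AlignmentError("taux and tauy are not on the same grid")
    lam = np.deg2rad(taux.lon)
    phi = np.deg2rad(taux.lat)
    cosphi = np.cos(phi)
    dtauy_dlam = np.gradient(tauy.values, lam, axis=2)
    dtaux_dphi = np.gradient(taux.values, phi, axis=1)
    curl = dtauy_dlam / (EARTH_RADIUS_M * cosphi[None, :, None]) - dtaux_dphi / EARTH_RADIUS_M
    return GriddedField(
        name="wind_stress_curl",
        units="N m-3",
        lat=taux.lat,
        lon=taux.lon,
        time=taux.time,
        values=curl,
        mask=taux.mask & tauy.mask,
    )


# ---------------------------------------------------------------------------
# Coastal paths


@dataclass
class CoastalPath:
    """An ordered list of (lat, lon) waypoints with monotonic path labels."""

    points: list[tuple[float, float]]
    labels: np.ndarray
    name: str = "path"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.points) != len(self.labels):
            raise ConfigError("points and labels must have equal length")
        d = np.diff(self.labels)
        if len(d) and not np.all(d > 0):
            raise ConfigError("path labels must be strictly increasing")


def meridional_coast_path(
    lats: np.ndarray, coast_lon: float = 0.0, offset: float = -0.5, name: str = "coast"
) -> CoastalPath:
    """Path running poleward just offshore of an idealized meridional coast."""
    lats = np.asarray(lats, dtype=float)
    pts = [(float(la), coast_lon + offset) for la in lats]
    return CoastalPath(points=pts, labels=lats, name=name)


def extract_along_path(
    field: GriddedField, path: CoastalPath, band_width: float
) -> np.ndarray:
    """Per path point, mean over ocean cells within ``band_width`` degrees.

    Distance is Euclidean in degrees with the longitude difference scaled
    by cos(latitude).  Returns a ``[time, position]`` array; positions with
    no ocean cell in range are NaN columns.
    """
    if band_width <= 0:
        raise ConfigError("band_width must be positive")
    nt = len(field.time)
    out = np.full((nt, len(path.points)), np.nan)
    lat2d = field.lat[:, None] * np.ones_like(field.lon)[None, :]
    lon2d = np.ones_like(field.lat)[:, None] * field.lon[None, :]
    for k, (plat, plon) in enumerate(path.points):
        dlat = lat2d - plat
        dlon = (lon2d - plon) * math.cos(math.radians(plat))
        near = (dlat**2 + dlon**2 <= band_width**2) & field.mask
        if not near.any():
            continue
        sub = field.values[:, near]
        with np.errstate(invalid="ignore"):
            cnt = np.isfinite(sub).sum(axis=1)
            s = np.nansum(sub, axis=1)
        out[:, k] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return out
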