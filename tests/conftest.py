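import numpy as np
import pandas as pd
import pytest

from upwell.grids import GriddedField, month_range


def make_field(
    values,
    lat=None,
    lon=None,
    start="2003-01",
    name="var",
    units="u",
    mask=None,
):
    values = np.asarray(values, dtype=float)
    nt, nlat, nlon = values.shape
    if lat is None:
        lat = np.arange(nlat, dtype=float)
    if lon is None:
        lon = np.arange(nlon, dtype=float) - nlon
    return GriddedField(
        name=name,
        units=units,
        lat=lat,
        lon=lon,
        time=month_range(start, nt),
        values=values,
        mask=mask,
    )


@pytest.fixture
def field_factory():
    return make_field


@pytest.fixture
def uniform_field():
    def _make(value, nt=36, nlat=4, nlon=5, **kwargs):
        return make_field(np.full((nt, nlat, nlon), float(value)), **kwargs)

    return _make


@pytest.fixture
def monthly_series():
    def _make(values, start="2003-01", name="s"):
        values = np.asarray(values, dtype=float)
        idx = pd.DatetimeIndex(month_range(start, len(values)))
        return pd.Series(values, index=idx, name=name)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
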