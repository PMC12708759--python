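import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upwell import anomalies
from upwell.anomalies import (
    anomaly_series,
    deseasonalize,
    detrend_series,
    detrended_anomalies,
    monthly_climatology,
    monthly_std,
    pooled_std,
    remove_linear_trend,
    seasonal_mean,
)
from upwell.errors import ConfigError, DataError


def cycle_values(nt, amplitude=1.0, phase=0.7):
    t = np.arange(nt, dtype=float)
    return amplitude * np.sin(2 * np.pi * t / 12 + phase)


class TestRemoveLinearTrend:
    def test_linear_series_to_zeros(self, field_factory):
        t = np.arange(48.0)
        vals = np.broadcast_to((2.0 + 0.3 * t)[:, None, None], (48, 2, 2)).copy()
        out = remove_linear_trend(field_factory(vals))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_constant_series_to_zeros(self, uniform_field):
        out = remove_linear_trend(uniform_field(5.0, nt=36))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_slope_intercept_allow_reconstruction(self, field_factory, rng):
        vals = rng.standard_normal((60, 3, 3))
        f = field_factory(vals)
        out = remove_linear_trend(f)
        t = np.arange(60.0)[:, None, None]
        rec = out.values + out.trend_slope[None] * t + out.trend_intercept[None]
        np.testing.assert_allclose(rec, vals, atol=1e-10)

    def test_too_short_record(self, uniform_field):
        with pytest.raises(DataError):
            remove_linear_trend(uniform_field(1.0, nt=12))

    def test_cell_with_too_few_points_missing(self, field_factory, rng):
        vals = rng.standard_normal((36, 2, 2))
        vals[1:, 0, 0] = np.nan
        out = remove_linear_trend(field_factory(vals))
        assert np.isnan(out.values[:, 0, 0]).all()


class TestMonthlyClimatology:
    def test_constant_field(self, uniform_field):
        clim = monthly_climatology(uniform_field(4.2, nt=36))
        np.testing.assert_allclose(clim, 4.2, rtol=1e-14)

    def test_pure_cycle_recovered_exactly(self, field_factory):
        s = cycle_values(60)
        f = field_factory(np.broadcast_to(s[:, None, None], (60, 2, 2)).copy())
        clim = monthly_climatology(f)
        np.testing.assert_allclose(clim[:, 0, 0], s[:12], atol=1e-12)

    def test_noise_shrinks_with_years_clt(self, field_factory, rng):
        n_years = 200
        sigma = 0.5
        s = cycle_values(12 * n_years)
        noise = rng.normal(0, sigma, 12 * n_years)
        f = field_factory((s + noise)[:, None, None])
        clim = monthly_climatology(f)
        err = np.abs(clim[:, 0, 0] - s[:12])
        assert (err < 3 * sigma / np.sqrt(n_years)).all()

    def test_fully_missing_month(self, field_factory):
        vals = np.ones((36, 1, 1))
        months = pd.DatetimeIndex(
            pd.date_range("2003-01", periods=36, freq="MS")
        ).month.to_numpy()
        vals[months == 7] = np.nan
        clim = monthly_climatology(field_factory(vals))
        assert np.isnan(clim[6, 0, 0])
        assert np.isfinite(np.delete(clim[:, 0, 0], 6)).all()


class TestDeseasonalize:
    def test_pure_cycle_to_zeros(self, field_factory):
        s = cycle_values(72)
        out = deseasonalize(field_factory(s[:, None, None]))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_delta_pulse_leakage(self, field_factory):
        # a single pulse of height p in one calendar month leaks -p/n_years
        # into every other year of that month
        n_years, p = 6, 3.0
        vals = np.zeros((12 * n_years, 1, 1))
        vals[14, 0, 0] = p  # March of year 2
        out = deseasonalize(field_factory(vals))
        got = out.values[:, 0, 0]
        march = np.arange(2, 12 * n_years, 12)
        np.testing.assert_allclose(got[14], p - p / n_years, atol=1e-12)
        others = march[march != 14]
        np.testing.assert_allclose(got[others], -p / n_years, atol=1e-12)

    def test_idempotent(self, field_factory, rng):
        f = field_factory(rng.standard_normal((60, 2, 2)))
        once = deseasonalize(f)
        twice = deseasonalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)


class TestDetrendedAnomalies:
    def test_trend_plus_cycle_to_zeros(self, field_factory):
        t = np.arange(252.0)
        vals = 1.0 + 0.02 * t + cycle_values(252)
        out = detrended_anomalies(field_factory(vals[:, None, None]))
        assert np.nanmax(np.abs(out.values)) < 1e-8

    def test_refit_slope_negligible(self, field_factory, rng):
        vals = rng.standard_normal((252, 2, 2)) + 0.01 * np.arange(252.0)[:, None, None]
        out = detrended_anomalies(field_factory(vals))
        _, slope, _ = anomalies._detrend_array(out.values)
        scale = np.nanmax(np.abs(vals))
        assert np.nanmax(np.abs(slope)) < 1e-10 * scale

    def test_climatology_of_output_is_zero(self, field_factory, rng):
        out = detrended_anomalies(field_factory(rng.standard_normal((120, 2, 2))))
        clim = monthly_climatology(out)
        assert np.nanmax(np.abs(clim)) < 1e-10

    def test_anomalies_sum_to_zero(self, field_factory, rng):
        out = detrended_anomalies(field_factory(rng.standard_normal((120, 2, 2))))
        total = np.nansum(out.values, axis=0)
        assert np.abs(total).max() < 1e-8

    def test_cellwise_permutation_commutes(self, field_factory, rng):
        vals = rng.standard_normal((48, 2, 3))
        out = detrended_anomalies(field_factory(vals))
        perm = rng.permutation(3)
        out_p = detrended_anomalies(field_factory(vals[:, :, perm]))
        np.testing.assert_allclose(out_p.values, out.values[:, :, perm], atol=1e-12)

    def test_recovers_injected_anomalies(self, field_factory, rng):
        # anomalies that are trend- and climatology-free survive the pipeline
        nt = 240
        t = np.arange(float(nt))
        base = 2.0 + 0.01 * t + cycle_values(nt)
        anom = rng.standard_normal(nt)
        anom_clean = anomalies._joint_anomaly_array(
            anom[:, None], (np.arange(nt) % 12) + 1
        )[0][:, 0]
        vals = base + anom_clean
        out = detrended_anomalies(field_factory(vals[:, None, None]))
        np.testing.assert_allclose(out.values[:, 0, 0], anom_clean, atol=1e-6)


class TestMonthlyStd:
    def test_zero_anomalies(self, monthly_series):
        s = monthly_series(np.zeros(48))
        np.testing.assert_allclose(monthly_std(s), 0.0, atol=1e-14)

    def test_gaussian_concentration(self):
        sigma = 0.7
        rng = np.random.default_rng(7)
        vals = monthly_std(
            rng.normal(0, sigma, 500 * 12),
            months=(np.arange(500 * 12) % 12) + 1,
        )
        assert np.all(np.abs(vals - sigma) < 0.05 * sigma)

    def test_alternating_closed_form(self, monthly_series):
        # one calendar month alternates +/-a over n years: std = a*sqrt(n/(n-1))
        n_years, a = 8, 2.0
        vals = np.zeros(12 * n_years)
        vals[np.arange(0, 12 * n_years, 12)] = a * (-1) ** np.arange(n_years)
        s = monthly_series(vals)
        out = monthly_std(s)
        np.testing.assert_allclose(out[0], a * np.sqrt(n_years / (n_years - 1)), rtol=1e-12)

    def test_single_year_missing(self, monthly_series):
        out = monthly_std(monthly_series(np.arange(12.0)))
        assert np.isnan(out).all()


class TestSeasonalMean:
    def test_constant_series(self, monthly_series):
        s = monthly_series(np.full(60, 2.5))
        out = seasonal_mean(s, (3, 4, 5))
        np.testing.assert_allclose(out.to_numpy(), 2.5, rtol=1e-14)

    def test_month_number_series_mam(self, monthly_series):
        idx = pd.date_range("2003-01", periods=60, freq="MS")
        s = pd.Series(idx.month.to_numpy(dtype=float), index=idx)
        out = seasonal_mean(s, "MAM")
        np.testing.assert_allclose(out.to_numpy(), 4.0, rtol=1e-14)

    def test_djf_first_year_missing(self, monthly_series):
        s = monthly_series(np.ones(36), start="2003-01")
        out = seasonal_mean(s, "DJF")
        assert np.isnan(out.loc[2003])
        np.testing.assert_allclose(out.loc[2004], 1.0)

    def test_empty_month_set_rejected(self, monthly_series):
        with pytest.raises(ConfigError):
            seasonal_mean(monthly_series(np.ones(24)), ())


class TestSeriesHelpers:
    def test_anomaly_series_matches_field_path(self, field_factory, monthly_series, rng):
        vals = rng.standard_normal(120)
        s = monthly_series(vals)
        f = field_factory(vals[:, None, None])
        np.testing.assert_allclose(
            anomaly_series(s).to_numpy(),
            detrended_anomalies(f).values[:, 0, 0],
            atol=1e-12,
        )

    def test_detrend_series_zero_slope(self, monthly_series, rng):
        out = detrend_series(monthly_series(rng.standard_normal(60)))
        slope = np.polyfit(np.arange(60), out.to_numpy(), 1)[0]
        assert abs(slope) < 1e-12

    def test_pooled_std_requires_two_points(self, monthly_series):
        with pytest.raises(DataError):
            pooled_std(np.array([1.0]))


@settings(max_examples=25, deadline=None)
@given(
    slope=st.floats(-1, 1, allow_nan=False),
    intercept=st.floats(-10, 10, allow_nan=False),
    amp=st.floats(0, 5, allow_nan=False),
    phase=st.floats(0, 6.28, allow_nan=False),
)
def test_property_trend_cycle_annihilated(slope, intercept, amp, phase):
    t = np.arange(120.0)
    vals = intercept + slope * t + amp * np.sin(2 * np.pi * t / 12 + phase)
    months = (np.arange(120) % 12) + 1
    out, *_ = anomalies._joint_anomaly_array(vals[:, None], months)
    scale = max(1.0, np.abs(vals).max())
    assert np.nanmax(np.abs(out)) < 1e-8 * scale
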