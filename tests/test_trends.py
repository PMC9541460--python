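"""DHW-difference trajectories, quadratic warming fit, slope maps."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from reefugia.refugia import classify_refugia, climatological_mean_dhw
from reefugia.trends import (atmos_change, detect_bleaching_years,
                             dhw_difference, fit_diff_vs_warming,
                             relative_warming_slope, rolling_mean,
                             warming_anomaly)

from conftest import make_annual_max


def _mask(bools):
    bools = np.asarray(bools, dtype=bool)
    return xr.Dataset({"is_refugium": (("lat", "lon"), bools),
                       "valid": (("lat", "lon"), np.ones_like(bools))})


class TestDhwDifference:
    def test_constant_groups(self):
        vals = np.full((3, 2, 4), 5.0)
        vals[:, :, :2] = 2.0
        am = make_annual_max(vals)
        mask = _mask([[True, True, False, False]] * 2)
        np.testing.assert_allclose(dhw_difference(am, mask).values, 3.0)

    def test_identical_distributions_give_zero(self):
        vals = np.tile(np.array([1.0, 7.0, 1.0, 7.0]), (3, 2, 1))
        am = make_annual_max(vals)
        mask = _mask([[True, True, False, False]] * 2)
        np.testing.assert_allclose(dhw_difference(am, mask).values, 0.0)

    def test_matches_two_group_median_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.random((6, 3, 5)) * 9
        am = make_annual_max(vals)
        ref = rng.random((3, 5)) < 0.4
        ref[0, 0] = True
        ref[2, 4] = False
        mask = _mask(ref)
        got = dhw_difference(am, mask).values
        for k in range(6):
            expected = np.median(vals[k][~ref]) - np.median(vals[k][ref])
            assert got[k] == pytest.approx(expected)

    def test_mean_aggregate_option(self):
        rng = np.random.default_rng(2)
        vals = rng.random((2, 2, 4))
        am = make_annual_max(vals)
        ref = np.array([[True, False, False, False]] * 2)
        got = dhw_difference(am, _mask(ref), aggregate="mean").values
        for k in range(2):
            assert got[k] == pytest.approx(vals[k][~ref].mean()
                                           - vals[k][ref].mean())

    def test_empty_group_rejected(self):
        am = make_annual_max(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="non-empty"):
            dhw_difference(am, _mask(np.ones((2, 2), dtype=bool)))


class TestRollingMean:
    def _series(self, vals):
        return xr.DataArray(np.asarray(vals, dtype=float), dims=("year",),
                            coords={"year": np.arange(2000, 2000 + len(vals))})

    def test_constant_series_unchanged(self):
        out = rolling_mean(self._series(np.full(30, 2.0)), window=11)
        np.testing.assert_allclose(out.values[5:-5], 2.0)
        assert np.isnan(out.values[:5]).all() and np.isnan(out.values[-5:]).all()

    def test_linear_series_unchanged_in_interior(self):
        x = np.arange(30, dtype=float)
        out = rolling_mean(self._series(x), window=11)
        np.testing.assert_allclose(out.values[5:-5], x[5:-5])

    def test_matches_windowed_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.random(40)
        out = rolling_mean(self._series(x), window=7).values
        for k in range(3, 37):
            assert out[k] == pytest.approx(x[k - 3:k + 4].mean())

    def test_commutes_with_constant_shift(self):
        rng = np.random.default_rng(4)
        x = rng.random(25)
        a = rolling_mean(self._series(x), window=5).values
        b = rolling_mean(self._series(x + 3.7), window=5).values
        np.testing.assert_allclose(b, a + 3.7)

    def test_even_or_oversized_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            rolling_mean(self._series(np.zeros(20)), window=10)
        with pytest.raises(ValueError, match="exceeds"):
            rolling_mean(self._series(np.zeros(5)), window=11)


class TestWarmingAnomaly:
    def _tas(self, vals, start=1860):
        return pd.Series(vals, index=pd.Index(
            np.arange(start, start + len(vals)), name="year"), name="tas")

    def test_constant_series_zero_anomaly(self):
        tas = self._tas(np.full(241, 14.0))
        np.testing.assert_allclose(warming_anomaly(tas).values, 0.0)

    def test_endpoint_anomaly(self):
        vals = np.full(241, 14.0)
        vals[-1] = 17.0
        anom = warming_anomaly(self._tas(vals))
        assert anom.loc[2100] == pytest.approx(3.0)

    def test_incomplete_baseline_rejected(self):
        tas = self._tas(np.full(150, 14.0), start=1951)
        with pytest.raises(ValueError, match="baseline"):
            warming_anomaly(tas)


class TestQuadraticFit:
    def test_noiseless_line_recovers_crossing_at_3(self):
        w = np.linspace(0.2, 4.0, 40)
        d = 1.5 - 0.5 * w
        fit = fit_diff_vs_warming(w, d)
        assert abs(fit.coefficients[2]) < 1e-10
        assert fit.crossing == pytest.approx(3.0, abs=1e-8)

    def test_constant_positive_diff_has_no_crossing(self):
        w = np.linspace(0.2, 4.0, 40)
        fit = fit_diff_vs_warming(w, np.full(40, 1.2))
        assert fit.crossing is None

    def test_noisy_quadratic_recovery(self):
        rng = np.random.default_rng(5)
        w = np.linspace(0.3, 4.5, 300)
        truth = -0.4 * (w - 0.5) * (w - 3.0)
        d = truth + 0.15 * rng.normal(size=len(w))
        fit = fit_diff_vs_warming(w, d)
        assert fit.crossing == pytest.approx(3.0, abs=0.15)

    def test_prediction_band_positive(self):
        rng = np.random.default_rng(6)
        w = rng.random(50) * 4
        d = 1 - w + 0.1 * rng.normal(size=50)
        fit = fit_diff_vs_warming(w, d)
        assert (fit.prediction_se(np.linspace(0, 4, 10)) > 0).all()

    def test_too_few_or_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_diff_vs_warming([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_diff_vs_warming(np.ones(10), np.arange(10.0))


class TestRelativeWarmingSlope:
    def _setup(self, cell_fn, years=(2014, 2033)):
        ny = years[1] - years[0] + 1
        vals = np.zeros((ny, 2, 3))
        base = np.linspace(3, 10, ny)  # shared baseline trajectory
        for k in range(ny):
            vals[k] = base[k]
            vals[k, 0, 0] = base[k] + cell_fn(years[0] + k)
        am = make_annual_max(vals, first_year=years[0])
        ref = np.zeros((2, 3), dtype=bool)
        ref[0, 0] = True
        return am, _mask(ref), years

    def test_cell_tracking_baseline_has_zero_slope(self):
        am, mask, years = self._setup(lambda y: 0.0)
        slope = relative_warming_slope(am, mask, period=years)
        assert slope.values[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert np.isnan(slope.values[1, 1])  # non-refugia cells undefined

    def test_linear_excess_warming_recovered(self):
        am, mask, years = self._setup(lambda y: 0.1 * (y - 2014))
        slope = relative_warming_slope(am, mask, period=years)
        assert slope.values[0, 0] == pytest.approx(0.1, abs=1e-8)

    def test_matches_per_cell_regression_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.random((20, 3, 4)) * 5
        am = make_annual_max(vals, first_year=2014)
        ref = np.zeros((3, 4), dtype=bool)
        ref[1, 1] = ref[2, 3] = True
        mask = _mask(ref)
        slope = relative_warming_slope(am, mask, period=(2014, 2033))
        years = np.arange(2014, 2034, dtype=float)
        baseline = np.array([np.median(vals[k][~ref]) for k in range(20)])
        for (i, j) in [(1, 1), (2, 3)]:
            resid = vals[:, i, j] - baseline
            expected = np.polyfit(years, resid, 1)[0]
            assert slope.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_too_short_period_rejected(self):
        am = make_annual_max(np.zeros((2, 2, 3)), first_year=2014)
        with pytest.raises(ValueError, match="3 years"):
            relative_warming_slope(am, _mask([[True, False, False]] * 2),
                                   period=(2014, 2015))


class TestBleachingConditions:
    def test_threshold_inclusive(self):
        med = xr.DataArray([1.9, 2.0, 3.5], dims=("year",),
                           coords={"year": [2000, 2001, 2002]})
        np.testing.assert_array_equal(detect_bleaching_years(med),
                                      [2001, 2002])

    def test_scaled_future_field_gives_plus_ten_percent(self):
        time = pd.date_range("1999-01-01", "2060-12-31", freq="D")
        base = np.ones(len(time))
        future = time.year >= 2045
        vals = np.where(future, 1.1, 1.0)
        field = xr.DataArray(vals[:, None, None], dims=("time", "lat", "lon"),
                             coords={"time": time, "lat": [-18.0],
                                     "lon": [146.0]})
        years = np.array([2005, 2010, 2052, 2055])
        change = atmos_change(field, years, present=(1999, 2019),
                              future=(2050, 2060))
        assert change.item() == pytest.approx(10.0)

    def test_generated_wind_dipole_sign_map(self, small_grid):
        """Percent change of wind during bleaching summers is positive in
        the northern half and negative in the southern half when the
        generator plants the future dipole."""
        from reefugia.synthetic import generate_forcing
        f = generate_forcing(small_grid, seed=6, years=(1995, 2100),
                             wind_dipole=0.15)
        change = atmos_change(f["wind_speed"],
                              np.array([2000, 2005, 2060, 2080]))
        lat = change["lat"].values
        north = lat > lat.mean()
        vals = change.values
        assert vals[north].mean() > 0
        assert vals[~north].mean() < 0

    def test_missing_bleaching_years_named(self):
        time = pd.date_range("1999-01-01", "2060-12-31", freq="D")
        field = xr.DataArray(np.ones(len(time))[:, None, None],
                             dims=("time", "lat", "lon"),
                             coords={"time": time, "lat": [-18.0],
                                     "lon": [146.0]})
        with pytest.raises(ValueError, match="future"):
            atmos_change(field, np.array([2005]), present=(1999, 2019),
                         future=(2050, 2060))
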