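"""Generator contracts: determinism, planted structure, trend recovery."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import reefugia as rf
from reefugia.synthetic import (GridConfig, SCENARIO_WARMING, generate_daily_sst,
                                generate_ensemble, generate_forcing,
                                generate_global_tas, generate_grid, scenario,
                                warming_path)


class TestGrid:
    def test_depths_within_shelf_range_and_enough_cells(self, small_grid):
        depths = small_grid["depth"].values[small_grid["mask"].values]
        assert depths.min() >= 4.0 and depths.max() <= 50.0
        assert small_grid["mask"].sum() >= 25

    def test_same_seed_bit_identical(self, small_grid_config):
        a = generate_grid(small_grid_config, seed=7)
        b = generate_grid(small_grid_config, seed=7)
        xr.testing.assert_identical(a, b)
        c = generate_grid(small_grid_config, seed=8)
        assert not np.array_equal(a["depth"].values, c["depth"].values)

    def test_too_few_cells_is_configuration_error(self):
        cfg = GridConfig(lon_min=145.0, lon_max=146.0, lat_min=-19.0,
                         lat_max=-18.0, resolution=0.5)
        with pytest.raises(ValueError, match="valid cells"):
            generate_grid(cfg, seed=0)

    def test_ill_ordered_bounds_rejected(self):
        with pytest.raises(ValueError, match="well-ordered"):
            generate_grid(GridConfig(lon_min=150.0, lon_max=145.0), seed=0)


class TestForcing:
    def test_zero_contrast_u0_homogeneous_up_to_noise(self, small_grid):
        f = generate_forcing(small_grid, mixing_contrast=0.0, seed=3,
                             years=(2000, 2001))
        u0 = f["u0"].values
        assert u0.std() / u0.mean() < 0.1

    def test_patches_have_higher_tidal_amplitude(self, small_grid):
        f = generate_forcing(small_grid, mixing_contrast=0.5, seed=7,
                             years=(2000, 2001))
        patch = f["high_mixing"].values
        u0 = f["u0"].values
        assert u0[patch].mean() > u0[~patch].mean()

    def test_negative_contrast_rejected(self, small_grid):
        with pytest.raises(ValueError, match="non-negative"):
            generate_forcing(small_grid, mixing_contrast=-0.1, seed=0)

    def test_wind_dipole_future_increase_north_decrease_south(self, small_grid):
        f = generate_forcing(small_grid, seed=5, years=(1995, 2100),
                             wind_dipole=0.15)
        w = f["wind_speed"]
        present = w.sel(time=slice("1995", "2014")).mean("time")
        future = w.sel(time=slice("2081", "2100")).mean("time")
        change = (future - present).values
        lat = f["lat"].values
        north = lat > lat.mean()
        assert change[north].mean() > 0
        assert change[~north].mean() < 0

    def test_forcing_fields_non_negative(self, small_forcing):
        assert float(small_forcing["u0"].min()) >= 0
        assert float(small_forcing["wind_speed"].min()) >= 0
        assert float(small_forcing["shortwave"].min()) >= 0


class TestDailySST:
    def test_noise_free_run_is_exact_seasonal_harmonic(self, small_grid):
        f = generate_forcing(small_grid, seed=1, years=(2000, 2002))
        spec = scenario("SSP5-8.5", seed=1, warming_2100=0.0,
                        noise_sigma=0.0, heatwave_rate=0.0, mean_advantage=0.0)
        sst = generate_daily_sst(small_grid, f, spec, years=(2000, 2002))
        t = pd.DatetimeIndex(sst["time"].values)
        days = (t - pd.Timestamp("1950-01-01")).days.to_numpy()
        lat = sst["lat"].values
        expected = (29.0 - 0.25 * (lat - lat.max()))[None, :, None] + \
            2.75 * np.cos(2 * np.pi * (days - 25) / 365.25)[:, None, None]
        mask = small_grid["mask"].values
        got = sst.values[:, mask]
        want = np.broadcast_to(expected, sst.shape)[:, mask]
        np.testing.assert_allclose(got, want, atol=1e-4)

    def test_same_spec_bit_identical(self, small_grid):
        f = generate_forcing(small_grid, seed=2, years=(2000, 2001))
        spec = scenario("SSP1-2.6", seed=9)
        a = generate_daily_sst(small_grid, f, spec, years=(2000, 2001))
        b = generate_daily_sst(small_grid, f, spec, years=(2000, 2001))
        xr.testing.assert_identical(a, b)

    def test_calendar_mismatch_raises(self, small_grid):
        f = generate_forcing(small_grid, seed=1, years=(2000, 2001))
        spec = scenario("SSP1-1.9", seed=1)
        with pytest.raises(ValueError, match="calendar"):
            generate_daily_sst(small_grid, f, spec, years=(1999, 2002))

    def test_strong_mixing_damps_summer_extremes(self, small_grid):
        """u0 = 0 everywhere vs u0 = 1 m/s everywhere, identical noise:
        the 99th percentile of summer SST is lower under strong mixing."""
        f0 = generate_forcing(small_grid, seed=4, years=(1985, 2019))
        spec = scenario("SSP1-1.9", seed=4)
        lo = f0.copy()
        lo["u0"] = xr.zeros_like(f0["u0"])
        hi = f0.copy()
        hi["u0"] = xr.ones_like(f0["u0"])
        sst_lo = generate_daily_sst(small_grid, lo, spec, years=(1985, 2019))
        sst_hi = generate_daily_sst(small_grid, hi, spec, years=(1985, 2019))
        summer = sst_lo["time"].dt.month.isin([12, 1, 2])
        mask = small_grid["mask"].values
        q_lo = np.nanpercentile(sst_lo.isel(time=summer).values[:, mask], 99)
        q_hi = np.nanpercentile(sst_hi.isel(time=summer).values[:, mask], 99)
        assert q_hi < q_lo

    def test_linear_trend_recovered_in_decadal_means(self, small_grid):
        f = generate_forcing(small_grid, seed=6, years=(1950, 2100))
        spec = scenario("SSP5-8.5", seed=6, warming_2100=4.0,
                        trend_shape="linear")
        sst = generate_daily_sst(small_grid, f, spec, years=(1950, 2100))
        domain = sst.where(small_grid["mask"]).mean(["lat", "lon"])
        first = float(domain.sel(time=slice("1950", "1959")).mean())
        last = float(domain.sel(time=slice("2091", "2100")).mean())
        yrs_first = np.arange(1950, 1960) + 0.5
        yrs_last = np.arange(2091, 2101) + 0.5
        planted = (warming_path(spec, yrs_last).mean()
                   - warming_path(spec, yrs_first).mean())
        assert abs((last - first) - planted) < 0.15  # weather noise at n=10yr

    def test_trend_slope_recovered_within_3_se(self, small_grid):
        f = generate_forcing(small_grid, seed=11, years=(1950, 2100))
        spec = scenario("SSP5-8.5", seed=11, warming_2100=4.0,
                        trend_shape="linear", mean_advantage=0.0)
        sst = generate_daily_sst(small_grid, f, spec, years=(1950, 2100))
        annual = (sst.where(small_grid["mask"]).mean(["lat", "lon"])
                  .resample(time="YS").mean())
        import statsmodels.api as sm
        y = annual.values
        x = sm.add_constant(np.arange(len(y), dtype=float))
        res = sm.OLS(y, x).fit()
        planted_slope = 4.0 / 150.0
        assert abs(res.params[1] - planted_slope) < 3 * res.bse[1]


class TestGlobalTas:
    def test_zero_warming_no_noise_is_flat(self):
        spec = scenario("SSP1-1.9", warming_2100=0.0)
        tas = generate_global_tas(spec, noise_sd=0.0)
        assert np.allclose(tas.values, tas.values[0])
        anom = rf.warming_anomaly(tas)
        assert np.allclose(anom.values, 0.0)

    def test_2100_anomaly_equals_configured_warming(self):
        spec = scenario("SSP3-7.0", warming_2100=3.0)
        tas = generate_global_tas(spec, noise_sd=0.0)
        anom = rf.warming_anomaly(tas)
        assert anom.loc[2100] == pytest.approx(3.0, abs=1e-9)

    def test_noise_reproducible_under_seed(self):
        spec = scenario("SSP5-8.5", seed=13)
        a = generate_global_tas(spec, noise_sd=0.1)
        b = generate_global_tas(spec, noise_sd=0.1)
        pd_equal = (a == b).all()
        assert pd_equal

    def test_scenario_warming_defaults_ordered(self):
        w = [SCENARIO_WARMING[s] for s in
             ("SSP1-1.9", "SSP1-2.6", "SSP3-7.0", "SSP5-8.5")]
        assert w[0] < w[1] < w[2] <= w[3]


class TestEnsemble:
    def test_member_count_and_distinct_ids(self, small_grid):
        f = generate_forcing(small_grid, seed=1, years=(2000, 2001))
        members = generate_ensemble(small_grid, f, n_models=5, base_seed=1,
                                    years=(2000, 2001))
        assert len(members) == 20  # 5 models x 4 scenarios
        ids = {(m.spec.scenario_id, m.spec.model_id) for m in members}
        assert len(ids) == 20

    def test_zero_perturbation_collapses_members(self, small_grid):
        f = generate_forcing(small_grid, seed=1, years=(2000, 2001))
        members = generate_ensemble(small_grid, f, ["SSP5-8.5"], n_models=3,
                                    base_seed=1, perturb_scale=0.0,
                                    years=(2000, 2001))
        xr.testing.assert_allclose(members[0].sst, members[1].sst)
        xr.testing.assert_allclose(members[0].sst, members[2].sst)

    def test_perturbation_spreads_2100_anomaly(self, small_grid):
        f = generate_forcing(small_grid, seed=1, years=(2000, 2001))
        members = generate_ensemble(small_grid, f, ["SSP5-8.5"], n_models=5,
                                    base_seed=1, perturb_scale=0.1,
                                    years=(2000, 2001), tas_noise_sd=0.0)
        finals = [rf.warming_anomaly(m.tas).loc[2100] for m in members]
        assert np.std(finals) > 0

    def test_duplicate_model_ids_rejected(self, small_grid):
        f = generate_forcing(small_grid, seed=1, years=(2000, 2001))
        with pytest.raises(ValueError, match="duplicate"):
            generate_ensemble(small_grid, f, ["SSP5-8.5"], n_models=2,
                              model_ids=["M1", "M1"], years=(2000, 2001))
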