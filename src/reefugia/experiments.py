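"""Canonical validation experiments on the synthetic ensemble.

These are the package's own calibration/consistency studies, run at a
desk-scale problem size (a ~10 × 12-cell reef window, 1985 onwards) so a
full multi-seed replication stays interactive:

* ``mechanism_consistency`` — does the planted mixing mechanism survive
  the full analysis chain? Per seed it checks that the top mixing-power
  quintile has lower climatological mean annual-max DHW than the bottom
  quintile, and that the refugia/non-refugia differences of tidal and
  wind mixing energy are positive.
* ``crossing_recovery`` — is the planted refugia-failure warming level
  recovered by the quadratic diff-vs-warming fit? Per seed a five-model
  high-emission ensemble is generated, classified, differenced and
  fitted; the recovered zero crossings are compared with the planted
  ``failure_warming``.
* ``scenario_persistence`` — qualitative trajectory behaviour: under
  low-warming scenarios the smoothed ensemble-mean difference stays
  positive through 2100; under high warming it crosses zero before 2100.
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr

from .climatology import climatology
from .energy_flux import compare_groups, summer_flux_mean, tidal_power, wind_mixing
from .refugia import classify_refugia, climatological_mean_dhw
from .synthetic import (GridConfig, _mixing_power, generate_daily_sst,
                        generate_ensemble, generate_forcing, generate_grid,
                        scenario)
from .thermal_stress import annual_max_dhw, dhw, hotspot
from .trends import dhw_difference, fit_diff_vs_warming, rolling_mean, warming_anomaly

__all__ = [
    "EVAL_GRID",
    "member_annual_max",
    "mechanism_consistency",
    "crossing_recovery",
    "scenario_persistence",
]

#: Desk-scale evaluation window used by the validation experiments.
EVAL_GRID = GridConfig(lon_min=145.0, lon_max=146.2, lat_min=-19.0,
                       lat_max=-18.0, resolution=0.1)


def _seed_for(base_seed: int, k: int) -> int:
    return int((base_seed * 100003 + k) % (2 ** 31 - 1))


def member_annual_max(grid, member):
    """Daily SST of one member → austral annual-max DHW (full chain)."""
    clim = climatology(member.sst)
    d = dhw(hotspot(member.sst, clim["mmm"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return annual_max_dhw(d)


def mechanism_consistency(n_seeds: int = 100, base_seed: int = 0,
                          grid_config: GridConfig = EVAL_GRID,
                          years: tuple[int, int] = (1985, 2020),
                          n_boot: int = 200) -> dict:
    """Fraction of seeds where the planted mixing mechanism shows through.

    Returns the fractions of seeds with (a) lower mean annual-max DHW in
    the top mixing-power quintile than the bottom, (b) positive
    refugia − non-refugia tidal-power difference, (c) positive wind
    mixing-flux difference (DJFM means of the bleaching summers).
    """
    ok_dhw = ok_tide = ok_wind = 0
    for k in range(n_seeds):
        seed = _seed_for(base_seed, k)
        grid = generate_grid(grid_config, seed=seed)
        forcing = generate_forcing(grid, seed=seed, years=years)
        spec = scenario("SSP3-7.0", seed=seed)
        sst = generate_daily_sst(grid, forcing, spec, years=years)
        clim = climatology(sst)
        d = dhw(hotspot(sst, clim["mmm"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            am = annual_max_dhw(d)
        mean_dhw = climatological_mean_dhw(am)
        mask = classify_refugia(mean_dhw, domain_mask=grid["mask"])

        power = _mixing_power(grid, forcing)
        valid = grid["mask"].values
        pv, mv = power[valid], mean_dhw.values[valid]
        top = pv >= np.quantile(pv, 0.8)
        bottom = pv <= np.quantile(pv, 0.2)
        ok_dhw += mv[top].mean() < mv[bottom].mean()

        p_tide = tidal_power(forcing["u0"]).where(grid["mask"])
        w_rate = wind_mixing(forcing["wind_speed"], grid["depth"])
        w_mean = summer_flux_mean(w_rate).where(grid["mask"])
        ok_tide += compare_groups(p_tide, mask["is_refugium"], grid["mask"],
                                  n_boot=n_boot, seed=seed).difference > 0
        ok_wind += compare_groups(w_mean, mask["is_refugium"], grid["mask"],
                                  n_boot=n_boot, seed=seed).difference > 0
    return {"n_seeds": n_seeds,
            "frac_quintile_dhw": float(ok_dhw) / n_seeds,
            "frac_tidal_positive": float(ok_tide) / n_seeds,
            "frac_wind_positive": float(ok_wind) / n_seeds}


def crossing_recovery(n_seeds: int = 20, base_seed: int = 0,
                      grid_config: GridConfig = EVAL_GRID,
                      n_models: int = 5,
                      years: tuple[int, int] = (1985, 2100),
                      planted: float = 3.0) -> dict:
    """Recover the planted failure warming level from the quadratic fit."""
    crossings = []
    for k in range(n_seeds):
        seed = _seed_for(base_seed, k)
        grid = generate_grid(grid_config, seed=seed)
        forcing = generate_forcing(grid, seed=seed, years=years)
        members = generate_ensemble(grid, forcing, ["SSP5-8.5"],
                                    n_models=n_models, base_seed=seed,
                                    years=years, failure_warming=planted)
        pooled_w, pooled_d = [], []
        for m in members:
            am = member_annual_max(grid, m)
            mask = classify_refugia(climatological_mean_dhw(am),
                                    domain_mask=grid["mask"])
            diff = dhw_difference(am, mask)
            anom = warming_anomaly(m.tas)
            yrs = diff["year"].values
            pooled_w.append(anom.reindex(yrs).values)
            pooled_d.append(diff.values)
        fit = fit_diff_vs_warming(np.concatenate(pooled_w),
                                  np.concatenate(pooled_d))
        crossings.append(fit.crossing)
    found = [c for c in crossings if c is not None]
    return {"n_seeds": n_seeds, "planted": planted, "crossings": crossings,
            "n_found": len(found),
            "mean_crossing": float(np.mean(found)) if found else None}


def scenario_persistence(n_seeds: int = 10, base_seed: int = 0,
                         grid_config: GridConfig = EVAL_GRID,
                         n_models: int = 5,
                         years: tuple[int, int] = (1985, 2100),
                         window: int = 11) -> dict:
    """Low scenarios keep a positive smoothed diff; high ones lose it.

    Per seed and scenario, the per-model diff series are smoothed with a
    centred rolling mean and averaged across models; the low-warming
    check requires the resulting series to stay strictly positive
    through 2100, the high-warming check requires it to reach zero or
    below before 2100.
    """
    pos_low = cross_high = 0
    for k in range(n_seeds):
        seed = _seed_for(base_seed, k)
        grid = generate_grid(grid_config, seed=seed)
        forcing = generate_forcing(grid, seed=seed, years=years)
        for sid, low in (("SSP1-1.9", True), ("SSP5-8.5", False)):
            members = generate_ensemble(grid, forcing, [sid],
                                        n_models=n_models, base_seed=seed,
                                        years=years)
            smoothed = []
            for m in members:
                am = member_annual_max(grid, m)
                mask = classify_refugia(climatological_mean_dhw(am),
                                        domain_mask=grid["mask"])
                smoothed.append(rolling_mean(dhw_difference(am, mask),
                                             window=window))
            ens = xr.concat(smoothed, dim="model").mean("model")
            vals = ens.dropna("year").values
            if low:
                pos_low += bool((vals > 0).all())
            else:
                cross_high += bool((vals <= 0).any())
    return {"n_seeds": n_seeds,
            "frac_low_positive": float(pos_low) / n_seeds,
            "frac_high_crossing": float(cross_high) / n_seeds}
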