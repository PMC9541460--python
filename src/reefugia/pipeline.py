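"""End-to-end orchestration: simulate → climatology → DHW → refugia →
mixing-energy comparison → warming-level trends.

The pipeline runs a full synthetic ensemble (default: 5 pseudo-models ×
4 SSP scenarios), computes each member's recentred climatology, DHW and
austral annual maxima, classifies refugia per member over the
historical window, builds per-scenario agreement maps, contrasts tidal
and wind mixing energy between a consensus refugia mask and the rest of
the domain, fits the pooled (warming, DHW-difference) quadratic per
scenario, and writes NetCDF/CSV/PNG outputs plus a machine-readable
JSON summary. Everything derives from the configured seeds, so a rerun
with the same config reproduces the same summary bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__, climatology as _clim_mod
from .climatology import climatology
from .energy_flux import compare_groups, summer_flux_mean, tidal_power, wind_mixing
from .io import config_hash, save_dataset, save_tas
from .refugia import classify_refugia, climatological_mean_dhw, model_agreement
from .synthetic import (GridConfig, generate_ensemble, generate_forcing,
                        generate_grid)
from .thermal_stress import annual_max_dhw, dhw, grid_median, hotspot
from .trends import (atmos_change, detect_bleaching_years, dhw_difference,
                     fit_diff_vs_warming, relative_warming_slope, rolling_mean,
                     warming_anomaly)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("reefugia")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    # domain (desk-scale default keeps a full ensemble interactive)
    lon_min: float = 145.0
    lon_max: float = 153.0
    lat_min: float = -22.0
    lat_max: float = -17.0
    resolution: float = 0.25
    # ensemble
    scenario_ids: list[str] = field(default_factory=lambda: [
        "SSP1-1.9", "SSP1-2.6", "SSP3-7.0", "SSP5-8.5"])
    n_models: int = 5
    years: tuple[int, int] = (1985, 2100)
    seed: int = 0
    perturb_scale: float = 0.1
    mixing_contrast: float = 0.5
    wind_dipole: float = 0.1
    # analysis
    clim_years: tuple[int, int] = (1985, 2012)
    centre_year: float = 1988.2857
    window_days: int = 84
    hotspot_floor: float = 1.0
    weekly_divisor: float = 7.0
    percentile: float = 0.20
    classification_period: tuple[int, int] = (1999, 2019)
    rolling_window: int = 11
    aggregate: str = "median"
    bleaching_summers: list[int] = field(default_factory=lambda: [2002, 2016, 2017])
    flux_months: list[int] = field(default_factory=lambda: [12, 1, 2, 3])
    n_boot: int = 2000
    block_size: int = 5
    min_agree: int = 2
    slope_period: tuple[int, int] = (2014, 2100)
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list) and f.name in (
                        "years", "clim_years", "classification_period",
                        "slope_period"):
                    v = tuple(v)
                kwargs[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = _time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage attribution
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name, _time.perf_counter() - t0)
            return out
        return run
    return wrap


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the report bundle under ``outdir``.

    Returns the machine-readable summary (also written as
    ``summary.json``): per-member refugia fractions and thresholds,
    per-scenario quadratic crossings, and the refugia/non-refugia flux
    contrasts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    config.to_yaml(outdir / "config.yaml")

    grid_cfg = GridConfig(lon_min=config.lon_min, lon_max=config.lon_max,
                          lat_min=config.lat_min, lat_max=config.lat_max,
                          resolution=config.resolution)

    @_stage("simulate")
    def simulate():
        grid = generate_grid(grid_cfg, seed=config.seed)
        forcing = generate_forcing(grid, mixing_contrast=config.mixing_contrast,
                                   seed=config.seed, years=config.years,
                                   wind_dipole=config.wind_dipole)
        members = generate_ensemble(grid, forcing, config.scenario_ids,
                                    n_models=config.n_models,
                                    base_seed=config.seed,
                                    perturb_scale=config.perturb_scale,
                                    years=config.years)
        save_dataset(grid, outdir / "grid.nc", seed=config.seed, config=cfg_dict)
        return grid, forcing, members

    grid, forcing, members = simulate()

    @_stage("climatology")
    def stage_clim():
        return {(m.spec.scenario_id, m.spec.model_id):
                climatology(m.sst, years=config.clim_years,
                            centre_year=config.centre_year)
                for m in members}

    mmm_by_member = stage_clim()

    @_stage("dhw")
    def stage_dhw():
        am = {}
        import warnings as _w
        for m in members:
            key = (m.spec.scenario_id, m.spec.model_id)
            hs = hotspot(m.sst, mmm_by_member[key]["mmm"])
            d = dhw(hs, window_days=config.window_days,
                    hotspot_floor=config.hotspot_floor,
                    weekly_divisor=config.weekly_divisor)
            with _w.catch_warnings():
                _w.simplefilter("ignore", UserWarning)
                am[key] = annual_max_dhw(d)
        return am

    annual_by_member = stage_dhw()

    @_stage("refugia")
    def stage_refugia():
        masks = {}
        for key, am in annual_by_member.items():
            mean_dhw = climatological_mean_dhw(am, config.classification_period)
            masks[key] = classify_refugia(mean_dhw, config.percentile,
                                          domain_mask=grid["mask"])
        agreement = {}
        for sid in config.scenario_ids:
            per_model = [masks[k] for k in masks if k[0] == sid]
            agreement[sid] = model_agreement(per_model)
            save_dataset(agreement[sid].to_dataset(name="n_agree"),
                         outdir / f"agreement_{sid}.nc", seed=config.seed,
                         config=cfg_dict)
        return masks, agreement

    masks, agreement = stage_refugia()

    @_stage("flux")
    def stage_flux():
        ref_sid = config.scenario_ids[0]
        need = min(config.min_agree, config.n_models)
        consensus = (agreement[ref_sid] >= need) & grid["mask"]
        consensus_ds = xr.Dataset({"is_refugium": consensus,
                                   "valid": grid["mask"]})
        p_tide = tidal_power(forcing["u0"]).where(grid["mask"])
        w_rate = wind_mixing(forcing["wind_speed"], grid["depth"])
        w_mean = summer_flux_mean(w_rate, years=config.bleaching_summers,
                                  months=config.flux_months).where(grid["mask"])
        cmp_tide = compare_groups(p_tide, consensus_ds["is_refugium"],
                                  grid["mask"], n_boot=config.n_boot,
                                  block_size=config.block_size, seed=config.seed)
        cmp_wind = compare_groups(w_mean, consensus_ds["is_refugium"],
                                  grid["mask"], n_boot=config.n_boot,
                                  block_size=config.block_size, seed=config.seed)
        save_dataset(xr.Dataset({"p_tide": p_tide, "wind_flux": w_mean,
                                 "consensus_refugium": consensus}),
                     outdir / "flux.nc", seed=config.seed, config=cfg_dict)
        return consensus_ds, cmp_tide, cmp_wind

    consensus_ds, cmp_tide, cmp_wind = stage_flux()

    @_stage("trends")
    def stage_trends():
        rows, fits, diff_series = [], {}, {}
        for sid in config.scenario_ids:
            pooled_w, pooled_d = [], []
            per_model_smoothed = []
            for m in members:
                if m.spec.scenario_id != sid:
                    continue
                key = (sid, m.spec.model_id)
                diff = dhw_difference(annual_by_member[key], masks[key],
                                      aggregate=config.aggregate)
                anom = warming_anomaly(m.tas)
                yrs = diff["year"].values
                pooled_w.append(anom.reindex(yrs).values)
                pooled_d.append(diff.values)
                per_model_smoothed.append(
                    rolling_mean(diff, config.rolling_window))
                rows += [{"scenario": sid, "model": m.spec.model_id,
                          "year": int(y), "diff": float(dv),
                          "warming": float(wv)}
                         for y, dv, wv in zip(yrs, diff.values,
                                              anom.reindex(yrs).values)]
            fit = fit_diff_vs_warming(np.concatenate(pooled_w),
                                      np.concatenate(pooled_d))
            fits[sid] = fit
            diff_series[sid] = xr.concat(per_model_smoothed, dim="model").mean("model")
        pd.DataFrame(rows).to_csv(outdir / "diff_vs_warming.csv", index=False)
        pd.DataFrame(
            [{"scenario": sid,
              "crossing_degC": fits[sid].crossing,
              "a0": fits[sid].coefficients[0],
              "a1": fits[sid].coefficients[1],
              "a2": fits[sid].coefficients[2]} for sid in fits]
        ).to_csv(outdir / "crossings.csv", index=False)

        # SSP5-8.5-style spatial trends and bleaching-condition changes
        high = config.scenario_ids[-1]
        key = (high, members[-1].spec.model_id)
        slope = relative_warming_slope(annual_by_member[key], masks[key],
                                       period=config.slope_period)
        save_dataset(slope.to_dataset(name="slope"), outdir / "slope.nc",
                     seed=config.seed, config=cfg_dict)
        med = grid_median(annual_by_member[key], grid["mask"])
        bleach_years = detect_bleaching_years(med)
        atmos = {}
        for var in ("wind_speed", "shortwave"):
            try:
                atmos[var] = atmos_change(forcing[var], bleach_years,
                                          months=tuple(config.flux_months))
            except ValueError as exc:
                log.warning("atmos change for %s skipped: %s", var, exc)
        if atmos:
            save_dataset(xr.Dataset({k: v for k, v in atmos.items()}),
                         outdir / "atmos_change.nc", seed=config.seed,
                         config=cfg_dict)
        return fits, diff_series, bleach_years, atmos, slope

    fits, diff_series, bleach_years, atmos, slope = stage_trends()

    if config.make_figures:
        @_stage("figures")
        def figures():
            _make_figures(outdir, config, agreement, diff_series, fits,
                          masks, grid, slope, atmos)
        figures()

    summary = {
        "software_version": __version__,
        "config_hash": config_hash(cfg_dict),
        "seed": config.seed,
        "n_members": len(members),
        "refugia": {
            f"{sid}/{mid}": {
                "fraction": float(np.mean(
                    masks[(sid, mid)]["is_refugium"].values[
                        masks[(sid, mid)]["valid"].values])),
                "threshold_dhw": masks[(sid, mid)].attrs["threshold_value"],
            } for (sid, mid) in masks},
        "crossings_degC": {sid: fits[sid].crossing for sid in fits},
        "flux_difference": {
            "tidal_W_m2": {"difference": cmp_tide.difference, "se": cmp_tide.se,
                           "p_value": cmp_tide.p_value},
            "wind_W_m2": {"difference": cmp_wind.difference, "se": cmp_wind.se,
                          "p_value": cmp_wind.p_value}},
        "bleaching_years_high_scenario": [int(y) for y in bleach_years],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _make_figures(outdir, config, agreement, diff_series, fits, masks, grid,
                  slope=None, atmos=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sid0 = config.scenario_ids[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    agreement[sid0].where(grid["mask"]).plot(ax=ax, cmap="Purples",
                                             vmin=0, vmax=config.n_models)
    ax.set_title(f"Model agreement on refugia ({sid0}, "
                 f"{config.classification_period[0]}–{config.classification_period[1]})")
    fig.savefig(outdir / "fig_agreement.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for sid, series in diff_series.items():
        ax.plot(series["year"], series.values, label=sid)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("year")
    ax.set_ylabel("non-refugia − refugia DHW (°C-weeks)")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "fig_diff_trajectory.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for sid, fit in fits.items():
        w = np.linspace(*fit.warming_range, 100)
        y = fit.predict(w)
        se = fit.prediction_se(w)
        (line,) = ax.plot(w, y, label=sid)
        ax.fill_between(w, y - se, y + se, alpha=0.2, color=line.get_color())
        if fit.crossing is not None:
            ax.axvline(fit.crossing, ls=":", color=line.get_color(), lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("global warming above 1860–1880 (°C)")
    ax.set_ylabel("non-refugia − refugia DHW (°C-weeks)")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "fig_diff_vs_warming.png", dpi=120)
    plt.close(fig)

    if slope is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        slope.plot(ax=ax, cmap="RdBu_r", center=0)
        ax.set_title("relative warming slope of refugia cells "
                     f"({config.slope_period[0]}–{config.slope_period[1]})")
        fig.savefig(outdir / "fig_slope.png", dpi=120)
        plt.close(fig)

    if atmos:
        fig, axes = plt.subplots(1, len(atmos), figsize=(5 * len(atmos), 4))
        axes = np.atleast_1d(axes)
        for ax, (name, fld) in zip(axes, atmos.items()):
            fld.where(grid["mask"]).plot(ax=ax, cmap="RdBu_r", center=0)
            ax.set_title(f"{name}: bleaching-year DJFM % change")
        fig.tight_layout()
        fig.savefig(outdir / "fig_atmos_change.png", dpi=120)
        plt.close(fig)
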