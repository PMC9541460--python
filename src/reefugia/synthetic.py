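"""Synthetic downscaled-ensemble generator for a GBR-like shelf sea.

This module fabricates the inputs the rest of the pipeline consumes — a
rectilinear reef grid with bathymetry, static tidal-current amplitude and
daily atmospheric forcing, daily SST per (pseudo-model, scenario) member,
and matching global-mean surface air temperature trajectories — with the
statistical structure the downstream analysis assumes:

* a seasonal harmonic peaking in the austral summer (late January),
* a monotone, scenario-dependent warming trend,
* red (AR(1)) daily weather noise with spatial coherence,
* episodic heatwave pulses (Poisson-timed, 10–60 day half-sine events),
* and spatially structured tidal/wind mixing that damps thermal anomalies.

The damping is the planted refugia mechanism: cells sitting over strong
tidal/wind mixing experience attenuated anomalies, hence lower degree
heating weeks, and are the cells the percentile classifier should find.
The damping advantage decays linearly with the global warming level and
flips sign past a configurable failure level ``failure_warming`` (default
3 °C), so the two cell populations are statistically exchangeable exactly
at that warming level; the refugia-loss trajectory therefore crosses zero
there by construction.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import signal
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .energy_flux import tidal_power, wind_mixing

__all__ = [
    "SCENARIO_WARMING",
    "GridConfig",
    "ScenarioSpec",
    "EnsembleMember",
    "scenario",
    "generate_grid",
    "generate_forcing",
    "generate_daily_sst",
    "generate_global_tas",
    "generate_ensemble",
    "warming_path",
]

#: Default end-of-century warming (°C above the 1860–1880 mean) per SSP.
#: Synthetic defaults consistent with the low scenarios staying below
#: 1.5/2.0 °C by 2100; NOT results of any model.
SCENARIO_WARMING = {
    "SSP1-1.9": 1.4,
    "SSP1-2.6": 1.8,
    "SSP3-7.0": 3.8,
    "SSP5-8.5": 4.6,
}

SECONDS_PER_DAY = 86400.0
TROPICAL_YEAR = 365.25


@dataclass(frozen=True)
class GridConfig:
    """Geometry of the synthetic reef domain.

    The default is a desk-scale 50 × 80 cell window at 0.1° inside the
    GBR-like bounding box; shelf depths are restricted to 4–50 m, the
    range over which tidal stirring can plausibly ventilate the surface.
    """

    lon_min: float = 145.0
    lon_max: float = 153.0
    lat_min: float = -22.0
    lat_max: float = -17.0
    resolution: float = 0.1
    depth_min: float = 4.0
    depth_max: float = 50.0
    land_fraction: float = 0.15  # fraction of cells masked out
    min_cells: int = 25


@dataclass(frozen=True)
class ScenarioSpec:
    """One ensemble member: scenario identity plus weather/mechanism knobs.

    warming_2100
        °C above the 1860–1880 pre-industrial mean at year 2100.
    trend_shape
        "ramp" (flat pre-1880, slow historical rise, scenario divergence
        after 2014; monotone PCHIP) or "linear" (linear from 1950).
    noise_sigma / noise_ar1 / noise_smooth_sigma
        Marginal std-dev (°C), lag-1 autocorrelation and spatial smoothing
        length (cells) of the daily weather noise.
    heatwave_*
        Poisson rate (events/yr), gamma amplitude (mean °C, shape) and
        duration bounds (days) of episodic warm pulses.
    damping_max / damping_midpoint / damping_scale
        Anomaly-damping susceptibility: s(c) = damping_max *
        sigmoid((P(c) - midpoint) / scale) with P the per-cell mixing
        power (W/m²). Anomaly fluctuations are multiplied by
        1 - s(c)*(1 - W/W*).
    failure_warming
        W*: the global warming level (°C) at which the mixing advantage
        vanishes (and beyond which it reverses).
    mean_advantage
        Amplitude (°C) of the mean heat-export advantage of high-mixing
        cells: an SST offset s(c)·β·(W − W_r)(W − W*)/W*², with W_r the
        warming level at the climatology centre year. Negative (cooling)
        between the climatology era and W*, zero at both roots, warming
        beyond W* — so the mean advantage also flips sign exactly at the
        planted failure level, and its locally linear drift during the
        climatology window is absorbed by the recentring regression.
    """

    scenario_id: str = "SSP5-8.5"
    model_id: str = "M1"
    warming_2100: float = 4.6
    trend_shape: str = "ramp"
    trend_amplification: float = 1.0
    noise_sigma: float = 0.6
    noise_ar1: float = 0.8
    noise_smooth_sigma: float = 2.0
    heatwave_rate: float = 1.8
    heatwave_amp_mean: float = 1.5
    heatwave_amp_shape: float = 4.0
    heatwave_duration: tuple[int, int] = (10, 60)
    damping_max: float = 0.5
    damping_midpoint: float = 0.08
    damping_scale: float = 0.02
    failure_warming: float = 3.0
    mean_advantage: float = 2.5
    seed: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if isinstance(self.seed, (int, np.integer)):
            object.__setattr__(self, "seed", (int(self.seed),))
        if self.trend_shape not in ("ramp", "linear"):
            raise ValueError(f"unknown trend_shape {self.trend_shape!r}")
        lo, hi = self.heatwave_duration
        if not (0 < lo <= hi):
            raise ValueError("heatwave_duration must be 0 < lo <= hi")


def scenario(scenario_id: str, model_id: str = "M1", seed: int = 0,
             **overrides) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` with the default warming for an SSP."""
    if "warming_2100" not in overrides:
        try:
            overrides["warming_2100"] = SCENARIO_WARMING[scenario_id]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario_id!r}; pass warming_2100 "
                f"explicitly or use one of {sorted(SCENARIO_WARMING)}"
            ) from None
    return ScenarioSpec(scenario_id=scenario_id, model_id=model_id,
                        seed=(seed,), **overrides)


@dataclass
class EnsembleMember:
    spec: ScenarioSpec
    sst: xr.DataArray
    tas: pd.Series


# ---------------------------------------------------------------------------
# grid and forcing
# ---------------------------------------------------------------------------

def _ar1_filter(innov: np.ndarray, phi: float) -> np.ndarray:
    """AR(1)-filter innovations along axis 0, staying in single precision."""
    b = np.array([1.0], dtype=np.float32)
    a = np.array([1.0, -phi], dtype=np.float32)
    return signal.lfilter(b, a, innov, axis=0)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardised smooth Gaussian random field (mean 0, std 1)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return (f - f.mean()) / max(f.std(), 1e-12)


def generate_grid(config: GridConfig = GridConfig(), seed: int = 0) -> xr.Dataset:
    """Generate bathymetry and a domain mask on a rectilinear grid.

    Depths vary smoothly and are rescaled to exactly span
    ``[depth_min, depth_max]``; a smooth field thresholded at
    ``land_fraction`` carves out land/excluded cells.

    Raises
    ------
    ValueError
        If the bounds are ill-ordered, the resolution non-positive, or
        fewer than ``min_cells`` cells survive masking.
    """
    c = config
    if not (c.lon_min < c.lon_max and c.lat_min < c.lat_max):
        raise ValueError("grid bounds must be well-ordered")
    if c.resolution <= 0:
        raise ValueError("resolution must be positive")
    lon = np.arange(c.lon_min + c.resolution / 2, c.lon_max, c.resolution)
    lat = np.arange(c.lat_min + c.resolution / 2, c.lat_max, c.resolution)
    ny, nx = len(lat), len(lon)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))

    f = _smooth_field(rng, (ny, nx), sigma=max(min(ny, nx) / 10, 1.0))
    lo, hi = f.min(), f.max()
    depth = c.depth_min + (f - lo) / (hi - lo) * (c.depth_max - c.depth_min)

    g = _smooth_field(rng, (ny, nx), sigma=max(min(ny, nx) / 8, 1.0))
    mask = g > np.quantile(g, c.land_fraction)
    n_valid = int(mask.sum())
    if n_valid < c.min_cells:
        raise ValueError(
            f"only {n_valid} valid cells (< {c.min_cells}); refine the "
            "resolution or shrink land_fraction"
        )
    return xr.Dataset(
        {
            "depth": (("lat", "lon"), depth, {"units": "m", "long_name": "total water depth"}),
            "mask": (("lat", "lon"), mask),
        },
        coords={"lat": lat, "lon": lon},
        attrs={"resolution": c.resolution, "seed": seed},
    )


def generate_forcing(
    grid: xr.Dataset,
    mixing_contrast: float = 0.5,
    seed: int = 0,
    years: tuple[int, int] = (1950, 2100),
    wind_dipole: float = 0.1,
    u0_base: float = 0.3,
    wind_mean: float = 6.0,
    wind_patch_boost: float = 0.3,
    rho: float = 1025.0,
    rho_a: float = 1.2,
) -> xr.Dataset:
    """Generate tidal-current amplitude and daily wind/shortwave forcing.

    ``mixing_contrast`` scales designated high-mixing patches (roughly the
    strongest quartile of a smooth field) where the tidal amplitude is
    elevated by up to that fraction and the wind speed by up to
    ``wind_patch_boost`` times that fraction — the spatial structure that
    creates refugia downstream (both energy sources are stronger over
    refugia). ``wind_dipole`` plants a future north–south wind trend
    (strengthening north, weakening south, ramping 2015→2100).
    """
    if mixing_contrast < 0:
        raise ValueError("mixing_contrast must be non-negative")
    lat, lon = grid["lat"].values, grid["lon"].values
    ny, nx = len(lat), len(lon)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))

    # static tidal amplitude: weak multiplicative noise + smooth patches.
    # Patches preferentially sit over shallow water (mixed where shallow
    # and tidally energetic, per the h/u³ stratification criterion), so
    # both tidal and wind (∝1/h) mixing energy are elevated there.
    noise = _smooth_field(rng, (ny, nx), sigma=1.5) * 0.05
    depth = grid["depth"].values
    shallowness = -(depth - depth.mean()) / max(depth.std(), 1e-12)
    score = shallowness + 0.5 * _smooth_field(rng, (ny, nx),
                                              sigma=max(min(ny, nx) / 8, 1.0))
    patch_weight = 1.0 / (1.0 + np.exp(-(score - np.quantile(score, 0.75)) / 0.15))
    u0 = u0_base * (1.0 + noise) * (1.0 + mixing_contrast * patch_weight)
    u0 = np.clip(u0, 0.0, None)

    time = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    nt = len(time)
    days = (time - pd.Timestamp("1950-01-01")).days.to_numpy()
    phase = 2 * np.pi * (days - 25) / TROPICAL_YEAR  # peak late January

    # wind: seasonal (stronger in winter trades) + red noise, >= 0
    innov = rng.standard_normal((nt, ny, nx)).astype(np.float32)
    if ny > 2 and nx > 2:
        innov = gaussian_filter(innov, sigma=(0, 1.0, 1.0), mode="nearest")
    ar = _ar1_filter(innov, 0.7)
    wind = np.asarray(wind_mean - 1.0 * np.cos(phase)[:, None, None],
                      dtype=np.float32)
    ar *= np.float32(1.5 * np.sqrt(1 - 0.7 ** 2))
    wind = wind + ar
    wind *= (1.0 + wind_patch_boost * mixing_contrast * patch_weight
             ).astype(np.float32)[None]
    if wind_dipole:
        lat_mid = 0.5 * (lat[0] + lat[-1])
        sign = np.where(lat > lat_mid, 1.0, -1.0)[None, :, None]  # north = less negative lat
        yearf = time.year.to_numpy() + (time.dayofyear.to_numpy() - 1) / TROPICAL_YEAR
        ramp = np.clip((yearf - 2015.0) / 85.0, 0.0, 1.0)[:, None, None]
        wind = wind * (1.0 + wind_dipole * sign * ramp).astype(np.float32)
    np.clip(wind, 0.0, None, out=wind)

    innov2 = rng.standard_normal((nt, ny, nx)).astype(np.float32)
    sw = (230.0 + 50.0 * np.cos(phase)[:, None, None] + 30.0 * innov2)
    np.clip(sw, 0.0, None, out=sw)

    return xr.Dataset(
        {
            "u0": (("lat", "lon"), u0, {"units": "m s-1", "long_name": "tidal current amplitude"}),
            "wind_speed": (("time", "lat", "lon"), wind, {"units": "m s-1"}),
            "shortwave": (("time", "lat", "lon"), sw.astype(np.float32), {"units": "W m-2"}),
            "high_mixing": (("lat", "lon"), patch_weight > 0.5),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"rho": rho, "rho_a": rho_a, "seed": seed,
               "mixing_contrast": mixing_contrast, "wind_dipole": wind_dipole},
    )


# ---------------------------------------------------------------------------
# warming trajectories
# ---------------------------------------------------------------------------

_RAMP_KNOTS = (np.array([1860.0, 1880.0, 1950.0, 2014.0, 2100.0]),
               np.array([0.0, 0.0, 0.065, 0.196, 1.0]))


def warming_path(spec: ScenarioSpec, years: np.ndarray) -> np.ndarray:
    """Global warming level W(y) in °C above the 1860–1880 mean.

    ``years`` may be fractional. The trajectory is ``warming_2100`` times a
    normalised monotone shape that is zero through 1880 and one at 2100, so
    the 2100 anomaly equals ``warming_2100`` exactly.
    """
    years = np.asarray(years, dtype=float)
    if spec.trend_shape == "linear":
        s = np.clip((years - 1950.0) / 150.0, 0.0, None)
    else:
        kx, ky = _RAMP_KNOTS
        interp = PchipInterpolator(kx, ky, extrapolate=True)
        s = np.where(years <= 1880.0, 0.0, interp(np.clip(years, None, 2100.0)))
        # extend linearly past 2100 with the end slope
        past = years > 2100.0
        if past.any():
            slope = float(interp.derivative()(2100.0))
            s = np.where(past, 1.0 + slope * (years - 2100.0), s)
    return spec.warming_2100 * s


def generate_global_tas(
    spec: ScenarioSpec,
    years: tuple[int, int] = (1860, 2100),
    noise_sd: float = 0.08,
    base_temperature: float = 14.0,
) -> pd.Series:
    """Annual global-mean surface air temperature (°C), 1860–2100.

    The deterministic part is ``base_temperature + W(y)`` so its anomaly
    versus the 1860–1880 mean reaches ``warming_2100`` at 2100 exactly;
    ``noise_sd`` adds iid interannual noise.
    """
    yr = np.arange(years[0], years[1] + 1)
    tas = base_temperature + warming_path(spec, yr)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([*spec.seed, 37]))
        tas = tas + noise_sd * rng.standard_normal(len(yr))
    return pd.Series(tas, index=pd.Index(yr, name="year"), name="tas")


# ---------------------------------------------------------------------------
# daily SST
# ---------------------------------------------------------------------------

def _mixing_power(grid: xr.Dataset, forcing: xr.Dataset) -> np.ndarray:
    """Per-cell mixing power P = tidal + time-mean wind flux (W/m²)."""
    p_tide = tidal_power(forcing["u0"].values, rho=forcing.attrs.get("rho", 1025.0))
    w3 = np.mean(forcing["wind_speed"].values.astype(np.float64) ** 3, axis=0)
    p_wind = wind_mixing(np.cbrt(w3), grid["depth"].values,
                         rho_a=forcing.attrs.get("rho_a", 1.2))
    return p_tide + p_wind


def generate_daily_sst(
    grid: xr.Dataset,
    forcing: xr.Dataset,
    spec: ScenarioSpec,
    years: tuple[int, int] = (1950, 2100),
    seasonal_amplitude: float = 2.75,
    mean_sst_equator_edge: float = 29.0,
    lat_gradient: float = 0.25,
) -> xr.DataArray:
    """Generate one member's daily SST field.

    SST(c, t) = seasonal harmonic + regional warming trend
    + m(c, t) · (AR(1) noise + heatwave pulses), where
    m(c, t) = 1 − s(c)·(1 − W(t)/W*) attenuates anomalies over
    high-mixing cells while W < W* and amplifies them past W*.
    """
    time = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    ftime = forcing["time"]
    if (time[0] < ftime.values[0]) or (time[-1] > ftime.values[-1]):
        raise ValueError(
            f"forcing calendar {ftime.values[0]}..{ftime.values[-1]} does not "
            f"cover requested years {years[0]}..{years[1]}"
        )
    lat, lon = grid["lat"].values, grid["lon"].values
    ny, nx = len(lat), len(lon)
    nt = len(time)
    rng = np.random.default_rng(np.random.SeedSequence([*spec.seed, 53]))

    days = (time - pd.Timestamp("1950-01-01")).days.to_numpy()
    phase = 2 * np.pi * (days - 25) / TROPICAL_YEAR
    lat_mean = mean_sst_equator_edge - lat_gradient * (lat - lat.max())  # warmer north
    seasonal = (lat_mean[None, :, None]
                + seasonal_amplitude * np.cos(phase)[:, None, None])

    yearf = time.year.to_numpy() + (time.dayofyear.to_numpy() - 1) / TROPICAL_YEAR
    w_t = warming_path(spec, yearf)
    trend = spec.trend_amplification * w_t

    # anomalies: AR(1) noise
    anom = np.zeros((nt, ny, nx), dtype=np.float32)
    if spec.noise_sigma > 0:
        innov = rng.standard_normal((nt, ny, nx)).astype(np.float32)
        if spec.noise_smooth_sigma > 0 and ny > 2 and nx > 2:
            innov = gaussian_filter(
                innov, sigma=(0, spec.noise_smooth_sigma, spec.noise_smooth_sigma),
                mode="nearest")
            innov /= max(float(innov.std()), 1e-12)
        innov *= np.float32(spec.noise_sigma * np.sqrt(1.0 - spec.noise_ar1 ** 2))
        anom = _ar1_filter(innov, spec.noise_ar1)

    # heatwave pulses: Poisson-timed half-sine events, summer-weighted amps
    if spec.heatwave_rate > 0:
        n_years = years[1] - years[0] + 1
        n_events = rng.poisson(spec.heatwave_rate * n_years)
        starts = rng.integers(0, nt, size=n_events)
        lo, hi = spec.heatwave_duration
        durations = rng.integers(lo, hi + 1, size=n_events)
        amp_scale = spec.heatwave_amp_mean / spec.heatwave_amp_shape
        amps = rng.gamma(spec.heatwave_amp_shape, amp_scale, size=n_events)
        for s0, dur, amp in zip(starts, durations, amps):
            s1 = min(s0 + dur, nt)
            if s1 <= s0:
                continue
            mid = min(s0 + dur // 2, nt - 1)
            season_w = 0.25 + 0.75 * 0.5 * (1.0 + np.cos(phase[mid]))
            pulse = amp * season_w * np.sin(
                np.pi * (np.arange(s0, s1) - s0 + 0.5) / dur)
            spat = 1.0 + 0.3 * _smooth_field(rng, (ny, nx),
                                             sigma=max(min(ny, nx) / 6, 1.0))
            anom[s0:s1] += (pulse[:, None, None] * spat[None]).astype(np.float32)

    # Mixing-controlled damping of anomaly *fluctuations*. The multiplier
    # acts on deviations about the expected anomaly climatology e(t) (the
    # analytic mean of the heatwave process), not on the anomaly itself:
    # mixing redistributes episodic heat without altering the mean seasonal
    # heat input, so the recentred climatology (hence MMM) stays comparable
    # across mixing regimes and the planted failure level is not shifted by
    # baseline contamination.
    power = _mixing_power(grid, forcing)
    s_cell = spec.damping_max / (
        1.0 + np.exp(-(power - spec.damping_midpoint) / spec.damping_scale))
    mw = np.asarray(1.0 - w_t / spec.failure_warming, dtype=np.float32)
    lo, hi = spec.heatwave_duration
    season_w = 0.25 + 0.75 * 0.5 * (1.0 + np.cos(phase))
    e_t = (spec.heatwave_rate / TROPICAL_YEAR * 0.5 * (lo + hi)
           * spec.heatwave_amp_mean * (2.0 / np.pi) * season_w
           ).astype(np.float32)
    anom -= e_t[:, None, None]
    anom *= np.float32(1.0) - s_cell.astype(np.float32)[None] * mw[:, None, None]
    anom += e_t[:, None, None]

    # mean heat-export advantage: cooling between the climatology era and
    # W*, warming beyond; both roots pin the refugia-loss crossing at W*
    if spec.mean_advantage != 0.0:
        w_ref = float(warming_path(spec, np.array([1988.2857]))[0])
        gamma = (spec.mean_advantage * (w_t - w_ref) * (w_t - spec.failure_warming)
                 / spec.failure_warming ** 2)
        anom += (s_cell[None] * gamma[:, None, None]).astype(np.float32)

    anom += (seasonal + trend[:, None, None]).astype(np.float32)
    sst = anom
    da = xr.DataArray(
        sst, dims=("time", "lat", "lon"),
        coords={"time": time, "lat": lat, "lon": lon},
        name="sst",
        attrs={
            "units": "degC",
            "model_id": spec.model_id,
            "scenario_id": spec.scenario_id,
            "seed": list(spec.seed),
        },
    )
    return da.where(grid["mask"]) if "mask" in grid else da


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def generate_ensemble(
    grid: xr.Dataset,
    forcing: xr.Dataset,
    scenario_ids: Sequence[str] = tuple(SCENARIO_WARMING),
    n_models: int = 5,
    base_seed: int = 0,
    perturb_scale: float = 0.1,
    years: tuple[int, int] = (1950, 2100),
    model_ids: Sequence[str] | None = None,
    tas_noise_sd: float = 0.08,
    **spec_overrides,
) -> list[EnsembleMember]:
    """Generate an n_models × n_scenarios ensemble of SST + tas members.

    Each pseudo-model perturbs the end-of-century warming, weather-noise
    amplitude and heatwave rate multiplicatively (log-normal, scale
    ``perturb_scale``) and runs its own noise stream. With
    ``perturb_scale == 0`` all members of a scenario are identical by
    construction (shared parameters and stream).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if model_ids is None:
        model_ids = [f"M{i + 1}" for i in range(n_models)]
    if len(set(model_ids)) != len(model_ids):
        raise ValueError(f"duplicate model_ids: {sorted(model_ids)}")
    if len(model_ids) != n_models:
        raise ValueError("model_ids length must equal n_models")

    members: list[EnsembleMember] = []
    for si, sid in enumerate(scenario_ids):
        for mi, mid in enumerate(model_ids):
            prng = np.random.default_rng(
                np.random.SeedSequence([base_seed, 71, mi]))
            z = prng.standard_normal(3)
            if perturb_scale > 0:
                overrides = dict(
                    warming_2100=SCENARIO_WARMING.get(sid, 3.0)
                    * float(np.exp(perturb_scale * 0.5 * z[0])),
                    noise_sigma=0.6 * float(np.exp(perturb_scale * z[1])),
                    heatwave_rate=1.8 * float(np.exp(perturb_scale * z[2])),
                )
                member_seed = (base_seed, si, mi)
            else:
                overrides = {}
                member_seed = (base_seed, si)
            overrides.update(spec_overrides)
            spec = scenario(sid, model_id=mid, **overrides)
            spec = replace(spec, seed=member_seed)
            sst = generate_daily_sst(grid, forcing, spec, years=years)
            tas = generate_global_tas(spec, noise_sd=tas_noise_sd)
            members.append(EnsembleMember(spec=spec, sst=sst, tas=tas))
    return members
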