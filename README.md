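# reefugia

Thermal-stress refugia analysis for shelf-sea coral reef domains:
degree-heating-week (DHW) metrics from daily gridded SST, a recentred
Maximum Monthly Mean climatology, percentile-based climate-refugia
classification with multi-model agreement, tidal/wind mixing-energy
attribution, and refugia-loss trajectories expressed against the global
warming level. The package ships a synthetic downscaled-ensemble
generator (5 pseudo-models × 4 SSP scenarios of daily SST 1950–2100
over a GBR-like grid) so the whole chain is testable end to end with no
data download.

It is aimed at reef and coastal climate-impact researchers who want the
operational stress metrics and the refugia bookkeeping as tested,
composable library functions rather than one-off scripts.

## The metrics

For each cell, monthly-mean SST climatologies over 1985–2012 are
recentred by per-month linear regression evaluated at 1988.2857; the
maximum of the 12 recentred months is the **MMM**. The daily warm
anomaly (**HotSpot**) is max(SST − MMM, 0), and

```
DHW(t) = (1/7) · Σ_{τ = t−83 … t} HotSpot(τ) · 1[HotSpot(τ) ≥ 1 °C]      [°C-weeks]
```

Annual maxima are taken over austral years (Aug 1 – Jul 31).
**Refugia** are the cells whose 1999–2019 mean annual-max DHW lies at
or below the grid's 20th-percentile value. Mixing energy is compared
between refugia and non-refugia via

```
P_tide = 4 k_b ρ u0³ / (3π)          k_b = 0.003
|∂φ_wind/∂t| = δ k_s ρ_a w³ / h      k_s = 6.4·10⁻⁵, δ = 0.023
```

with spatial block-bootstrap uncertainty. Refugia loss is tracked by
the per-year (non-refugia − refugia) median annual-max DHW, pooled
against each model's global warming anomaly (vs 1860–1880) and fitted
with a second-degree polynomial whose downward zero crossing is the
warming level at which refugia fail.

## Worked example

```python
import reefugia as rf
from reefugia.synthetic import (GridConfig, generate_forcing,
                                generate_grid, generate_daily_sst, scenario)

grid = generate_grid(GridConfig(lon_min=145, lon_max=146.2,
                                lat_min=-19, lat_max=-18, resolution=0.1),
                     seed=1)
forcing = generate_forcing(grid, seed=1, years=(1985, 2020))
sst = generate_daily_sst(grid, forcing, scenario("SSP3-7.0", seed=1),
                         years=(1985, 2020))

clim = rf.climatology(sst)                       # 12 months + MMM
d = rf.dhw(rf.hotspot(sst, clim["mmm"]))
am = rf.annual_max_dhw(d)
mean_dhw = rf.climatological_mean_dhw(am)        # 1999–2019 mean
mask = rf.classify_refugia(mean_dhw, domain_mask=grid["mask"])

frac = mask["is_refugium"].values[mask["valid"].values].mean()
print(f"refugia fraction: {frac:.3f}")
print(f"threshold: {mask.attrs['threshold_value']:.2f} degC-weeks")

cmp = rf.compare_groups(rf.tidal_power(forcing["u0"]).where(grid["mask"]),
                        mask["is_refugium"], grid["mask"], seed=1)
print(f"tidal power, refugia - non-refugia: "
      f"{cmp.difference:.4f} +/- {cmp.se:.4f} W/m^2 (p = {cmp.p_value:.2g})")
```

prints

```
refugia fraction: 0.206
threshold: 0.73 degC-weeks
tidal power, refugia - non-refugia: 0.0625 +/- 0.0221 W/m^2 (p = 0.0047)
```

— about a fifth of the valid cells fall at or below the 20th-percentile
threshold (ties make it slightly more than 20 %), and the flagged cells
sit over significantly stronger tidal mixing, the planted mechanism.

The full pipeline (ensemble simulation → climatology → DHW → refugia →
flux → trends, with NetCDF/CSV/PNG outputs and a JSON summary) runs as

```
reefugia run --out report/ --seed 1
```

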