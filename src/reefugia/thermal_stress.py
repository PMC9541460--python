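"""HotSpots, degree heating weeks and their annual/spatial aggregation.

The thermal-stress currency of the analysis is the degree heating week
(DHW): each day's warm anomaly above the Maximum Monthly Mean (the
"HotSpot", floored at zero) is accumulated over a trailing 84-day
(12-week) window, counting only HotSpots of at least 1 °C — the level at
which coral thermal stress is conventionally taken to begin — and
converted from °C-days to °C-weeks by dividing by 7. Annual maxima are
taken over austral summer years (1 August – 31 July, labelled by the
ending calendar year) so that a Southern-Hemisphere summer is never
split between two analysis years.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "hotspot",
    "dhw",
    "annual_max_dhw",
    "grid_median",
    "ensemble_median",
    "WINDOW_DAYS_DEFAULT",
    "HOTSPOT_FLOOR_DEFAULT",
]

WINDOW_DAYS_DEFAULT = 84
HOTSPOT_FLOOR_DEFAULT = 1.0
WEEKLY_DIVISOR_DEFAULT = 7.0


def hotspot(sst: xr.DataArray, mmm: xr.DataArray) -> xr.DataArray:
    """Daily warm anomaly max(SST − MMM, 0) per cell."""
    for dim in mmm.dims:
        if dim not in sst.dims or sst.sizes[dim] != mmm.sizes[dim]:
            raise ValueError(f"SST and MMM grids differ on dimension {dim!r}")
    hs = xr.apply_ufunc(np.maximum, sst - mmm, 0.0)
    hs.name = "hotspot"
    hs.attrs["units"] = "degC"
    return hs


def dhw(
    hs: xr.DataArray,
    window_days: int = WINDOW_DAYS_DEFAULT,
    hotspot_floor: float = HOTSPOT_FLOOR_DEFAULT,
    weekly_divisor: float = WEEKLY_DIVISOR_DEFAULT,
) -> xr.DataArray:
    """Degree heating weeks: trailing-window sum of qualifying HotSpots.

    dhw(t) = Σ over the ``window_days`` days ending at t of
    HotSpot·1[HotSpot ≥ hotspot_floor], divided by ``weekly_divisor``
    (°C-days → °C-weeks). The first ``window_days − 1`` entries are NaN:
    an incomplete window is not a valid accumulation. The daily series
    must be gap-free.
    """
    t = pd.DatetimeIndex(hs["time"].values)
    if len(t) < window_days:
        raise ValueError(f"series shorter than the {window_days}-day window")
    deltas = np.diff(t.values).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        gap = t[int(np.argmax(deltas != 1))]
        raise ValueError(f"daily series has a gap after {gap.date()}")

    axis = hs.dims.index("time")
    vals = np.moveaxis(hs.values.astype(np.float64), axis, 0)
    qual = np.where(vals >= hotspot_floor, vals, 0.0)
    qual = np.nan_to_num(qual, nan=0.0)  # masked cells restored below
    csum = np.cumsum(qual, axis=0)
    out = np.full_like(csum, np.nan)
    out[window_days - 1] = csum[window_days - 1]
    out[window_days:] = csum[window_days:] - csum[:-window_days]
    out /= weekly_divisor
    # restore all-NaN (masked) cells
    cellnan = np.isnan(vals).all(axis=0)
    out[:, cellnan] = np.nan
    out = np.moveaxis(out, 0, axis)
    da = xr.DataArray(out, dims=hs.dims, coords=hs.coords, name="dhw")
    da.attrs.update({"units": "degC weeks", "window_days": window_days,
                     "hotspot_floor": hotspot_floor,
                     "weekly_divisor": weekly_divisor})
    return da


def _austral_year_labels(t: pd.DatetimeIndex) -> np.ndarray:
    """Austral year label: Aug 1 (y−1) … Jul 31 (y) → y."""
    return t.year.values + (t.month.values >= 8).astype(int)


def annual_max_dhw(d: xr.DataArray, convention: str = "austral") -> xr.DataArray:
    """Per-cell annual maximum DHW over complete austral (or calendar) years.

    Incomplete years at the series ends are excluded with a warning. NaNs
    inside a year (e.g. the accumulation spin-up) are skipped.
    """
    t = pd.DatetimeIndex(d["time"].values)
    if convention == "austral":
        labels = _austral_year_labels(t)

        def complete(y: int) -> bool:
            start = pd.Timestamp(year=y - 1, month=8, day=1)
            end = pd.Timestamp(year=y, month=7, day=31)
            return t[0] <= start and t[-1] >= end
    elif convention == "calendar":
        labels = t.year.values

        def complete(y: int) -> bool:
            return (t[0] <= pd.Timestamp(year=y, month=1, day=1)
                    and t[-1] >= pd.Timestamp(year=y, month=12, day=31))
    else:
        raise ValueError(f"unknown convention {convention!r}")

    years = np.unique(labels)
    keep = np.array([complete(int(y)) for y in years])
    if not keep.all():
        dropped = [int(y) for y in years[~keep]]
        warnings.warn(f"excluding partial {convention} years {dropped}",
                      stacklevel=2)
    years = years[keep]
    if len(years) == 0:
        raise ValueError("no complete years in the series")

    pieces = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for y in years:
            sel = d.isel(time=labels == y)
            pieces.append(sel.max("time", skipna=True))
    out = xr.concat(pieces, dim=pd.Index(years, name="year"))
    out.name = "annual_max_dhw"
    out.attrs.update({"units": "degC weeks", "convention": convention})
    return out


def grid_median(field: xr.DataArray, mask: xr.DataArray | None = None) -> xr.DataArray:
    """Spatial median over valid (masked-in) cells, per remaining dim."""
    if mask is not None:
        field = field.where(mask)
    spatial = [dim for dim in ("lat", "lon", "cell") if dim in field.dims]
    if not spatial:
        raise ValueError("no spatial dimensions to take the median over")
    med = field.median(spatial, skipna=True)
    if bool(med.isnull().all()):
        raise ValueError("spatial median undefined: no valid cells")
    return med


def ensemble_median(per_model: list[xr.DataArray], how: str = "mean") -> xr.DataArray:
    """Combine per-model spatial-median series into one ensemble series.

    Per-model annual grid medians are averaged across models (the default;
    a median across models is available via ``how="median"``).
    """
    if not per_model:
        raise ValueError("need at least one model series")
    stack = xr.concat(per_model, dim="model")
    if how == "mean":
        return stack.mean("model")
    if how == "median":
        return stack.median("model")
    raise ValueError(f"unknown aggregation {how!r}")
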