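"""Recentred monthly-mean SST climatology and its Maximum Monthly Mean.

The bleaching-relevant baseline for degree-heating-week accumulation is
the Maximum Monthly Mean (MMM): per cell, twelve monthly climatological
means are built from daily SST over 1985–2012, each month's 28 yearly
means are regressed linearly against calendar year, and the fitted line
is evaluated at 1988.2857. The fractional centre year is a convention
inherited from the original operational 7-year satellite climatology
(1985–1990 plus 1993, shifted to account for Mt Pinatubo aerosol years);
no special-casing beyond evaluating at that abscissa is involved. The
MMM is the maximum of the twelve recentred monthly values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "CENTRE_YEAR_DEFAULT",
    "monthly_means_by_year",
    "recentre_climatology",
    "compute_mmm",
    "climatology",
]

CENTRE_YEAR_DEFAULT = 1988.2857
CLIM_YEARS_DEFAULT = (1985, 2012)


def monthly_means_by_year(
    sst: xr.DataArray, years: tuple[int, int] = CLIM_YEARS_DEFAULT
) -> xr.DataArray:
    """Average daily SST into per-(year, month) means over the window.

    Every day of every month in ``years`` (inclusive) must be present;
    a month with no days raises, naming the gap. All days weigh equally
    (leap days included).
    """
    y0, y1 = years
    sub = sst.sel(time=slice(f"{y0}-01-01", f"{y1}-12-31"))
    t = pd.DatetimeIndex(sub["time"].values)
    expected = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    if len(t) == 0 or not expected.isin(t).all():
        missing = expected.difference(t)
        first = missing[0] if len(missing) else "?"
        raise ValueError(
            f"daily SST does not cover {y0}-{y1}: e.g. no data for "
            f"{pd.Timestamp(first).strftime('%Y-%m')}")
    m = sub.resample(time="MS").mean()
    mt = pd.DatetimeIndex(m["time"].values)
    m = m.assign_coords(year=("time", mt.year), month=("time", mt.month))
    m = m.set_index(time=["year", "month"]).unstack("time")
    return m.transpose("year", "month", ...)


def recentre_climatology(
    monthly: xr.DataArray, centre_year: float = CENTRE_YEAR_DEFAULT
) -> xr.DataArray:
    """Evaluate each month's year-regression at the centre year.

    For each cell and month, the yearly monthly means are fitted by
    ordinary least squares against the integer calendar year and the
    fitted value at ``centre_year`` becomes the climatological monthly
    mean. Exact for inputs linear in year.
    """
    years = monthly["year"].values.astype(float)
    if len(np.unique(years)) < 2:
        raise ValueError("need at least two distinct years to recentre")
    y = monthly.values  # (year, month, ...)
    x = years - years.mean()
    denom = (x ** 2).sum()
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        ybar = np.nanmean(y, axis=0)
    slope = np.tensordot(x, y - ybar, axes=(0, 0)) / denom
    fitted = ybar + slope * (centre_year - years.mean())
    out = xr.DataArray(
        fitted, dims=monthly.dims[1:],
        coords={k: v for k, v in monthly.coords.items() if k != "year"},
        name="climatology",
        attrs={"centre_year": centre_year, "units": "degC"},
    )
    return out


def compute_mmm(clim: xr.DataArray) -> xr.DataArray:
    """Maximum Monthly Mean: per-cell max of the 12 recentred months."""
    if clim.sizes.get("month", 0) != 12:
        raise ValueError("climatology must carry all 12 months")
    mmm = clim.max("month")
    mmm.name = "mmm"
    mmm.attrs.update({"units": "degC",
                      "centre_year": clim.attrs.get("centre_year")})
    return mmm


def climatology(
    sst: xr.DataArray,
    years: tuple[int, int] = CLIM_YEARS_DEFAULT,
    centre_year: float = CENTRE_YEAR_DEFAULT,
) -> xr.Dataset:
    """Daily SST → recentred monthly climatology + MMM in one call."""
    monthly = monthly_means_by_year(sst, years)
    clim = recentre_climatology(monthly, centre_year)
    mmm = compute_mmm(clim)
    return xr.Dataset({"climatology": clim, "mmm": mmm},
                      attrs={"centre_year": centre_year,
                             "climatology_years": list(years)})
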