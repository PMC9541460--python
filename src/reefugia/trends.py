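"""Refugia-loss trajectories against the global warming level.

The fate of refugia is tracked through the difference between
non-refugia and refugia aggregate annual-max DHW: while positive,
refugia experience less thermal stress than the rest of the domain.
The per-year difference is smoothed with a centred 11-year rolling mean
for trajectory plots; the unsmoothed (warming, difference) pairs from
every model are pooled and fitted with an ordinary-least-squares
second-degree polynomial in the global warming anomaly (°C above the
1860–1880 mean), whose first zero crossing inside the observed warming
range is the warming level at which refugia fail. Per-cell relative
warming slopes and bleaching-condition atmospheric changes complete the
spatial picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr

from .energy_flux import summer_flux_mean
from .thermal_stress import grid_median

__all__ = [
    "dhw_difference",
    "rolling_mean",
    "warming_anomaly",
    "fit_diff_vs_warming",
    "QuadraticFit",
    "relative_warming_slope",
    "detect_bleaching_years",
    "atmos_change",
]


def dhw_difference(
    annual_max: xr.DataArray, mask: xr.Dataset, aggregate: str = "median"
) -> xr.DataArray:
    """Per-year (non-refugia − refugia) aggregate annual-max DHW."""
    is_ref = mask["is_refugium"]
    valid = mask["valid"] if "valid" in mask else xr.ones_like(is_ref, dtype=bool)
    non_ref = valid & ~is_ref
    if not bool(is_ref.any()) or not bool(non_ref.any()):
        raise ValueError("both refugia and non-refugia groups must be non-empty")
    spatial = [d for d in ("lat", "lon", "cell") if d in annual_max.dims]
    agg = {"median": xr.DataArray.median, "mean": xr.DataArray.mean}
    try:
        f = agg[aggregate]
    except KeyError:
        raise ValueError(f"unknown aggregate {aggregate!r}") from None
    diff = (f(annual_max.where(non_ref), dim=spatial)
            - f(annual_max.where(is_ref), dim=spatial))
    diff.name = "dhw_difference"
    diff.attrs.update({"units": "degC weeks", "aggregate": aggregate})
    return diff


def rolling_mean(series: xr.DataArray, window: int = 11) -> xr.DataArray:
    """Centred moving average; incomplete-window ends are NaN."""
    if window % 2 != 1:
        raise ValueError("window must be odd for a centred mean")
    n = series.sizes[series.dims[0]]
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    return series.rolling({series.dims[0]: window}, center=True,
                          min_periods=window).mean()


def warming_anomaly(tas: pd.Series, baseline: tuple[int, int] = (1860, 1880)) -> pd.Series:
    """tas(y) minus the mean over the baseline years (inclusive)."""
    y0, y1 = baseline
    base = tas.loc[(tas.index >= y0) & (tas.index <= y1)]
    if len(base) < (y1 - y0 + 1):
        raise ValueError(f"baseline {y0}-{y1} incomplete in the tas series")
    out = tas - base.mean()
    out.name = "warming_anomaly"
    return out


@dataclass
class QuadraticFit:
    """OLS quadratic of diff on warming: diff ≈ a0 + a1·W + a2·W²."""
    coefficients: np.ndarray        # (a0, a1, a2)
    standard_errors: np.ndarray
    covariance: np.ndarray
    crossing: float | None          # warming level where fitted diff = 0
    warming_range: tuple[float, float]
    n_points: int

    def predict(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        a0, a1, a2 = self.coefficients
        return a0 + a1 * w + a2 * w ** 2

    def prediction_se(self, w: np.ndarray) -> np.ndarray:
        """Pointwise standard error of the fitted curve."""
        w = np.asarray(w, dtype=float)
        X = np.column_stack([np.ones_like(w), w, w ** 2])
        return np.sqrt(np.einsum("ij,jk,ik->i", X, self.covariance, X))


def fit_diff_vs_warming(warming, diff) -> QuadraticFit:
    """Fit the pooled (warming, diff) pairs with an OLS quadratic.

    The crossing is the smallest downward root of the fitted polynomial
    (fitted difference passing from positive to negative — refugia
    failing) above 0 °C and within the observed warming range; if no
    downward root lies there, the smallest root of any direction is
    taken, and ``None`` if the curve never reaches zero in range.
    """
    w = np.asarray(warming, dtype=float)
    d = np.asarray(diff, dtype=float)
    ok = np.isfinite(w) & np.isfinite(d)
    w, d = w[ok], d[ok]
    if len(w) < 6:
        raise ValueError(f"need at least 6 (warming, diff) pairs, have {len(w)}")
    X = sm.add_constant(np.column_stack([w, w ** 2]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: warming values too degenerate")
    res = sm.OLS(d, X).fit()
    a0, a1, a2 = res.params
    w_max = float(w.max())
    roots = np.roots([a2, a1, a0]) if abs(a2) > 1e-12 else (
        np.array([-a0 / a1]) if abs(a1) > 1e-12 else np.array([]))
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    in_range = [r for r in real if 0.0 < r <= w_max]
    downward = [r for r in in_range if a1 + 2 * a2 * r < 0]
    crossing = float(downward[0]) if downward else (
        float(in_range[0]) if in_range else None)
    return QuadraticFit(
        coefficients=np.array([a0, a1, a2]),
        standard_errors=np.asarray(res.bse),
        covariance=np.asarray(res.cov_params()),
        crossing=crossing,
        warming_range=(float(w.min()), w_max),
        n_points=len(w),
    )


def relative_warming_slope(
    annual_max: xr.DataArray,
    mask: xr.Dataset,
    baseline_mode: str = "non-refugia",
    period: tuple[int, int] = (2014, 2100),
) -> xr.DataArray:
    """Per-refugia-cell warming rate relative to the domain baseline.

    The baseline median annual-max DHW ("non-refugia" cells by default,
    or the whole grid with ``baseline_mode="grid"``) is subtracted per
    year from each refugia cell, and a least-squares line is fitted to
    each cell's residual series over ``period``; the slope (°C-weeks/yr)
    maps where refugia warm faster (positive) or slower (negative) than
    the domain at large.
    """
    y0, y1 = period
    sub = annual_max.sel(year=slice(y0, y1))
    if sub.sizes["year"] < 3:
        raise ValueError("need at least 3 years to fit a slope")
    is_ref = mask["is_refugium"]
    valid = mask["valid"] if "valid" in mask else xr.ones_like(is_ref, dtype=bool)
    if baseline_mode == "non-refugia":
        baseline = grid_median(sub.where(valid & ~is_ref))
    elif baseline_mode == "grid":
        baseline = grid_median(sub.where(valid))
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    resid = (sub - baseline).where(is_ref)

    years = sub["year"].values.astype(float)
    x = years - years.mean()
    y = resid.values  # (year, ...)
    axis = resid.dims.index("year")
    y = np.moveaxis(y, axis, 0)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        ymean = np.nanmean(y, axis=0)
    slope = np.tensordot(x, np.nan_to_num(y - ymean, nan=0.0),
                         axes=(0, 0)) / (x ** 2).sum()
    slope = np.where(np.isfinite(y).all(axis=0), slope, np.nan)
    dims = tuple(d for d in resid.dims if d != "year")
    out = xr.DataArray(slope, dims=dims,
                       coords={k: resid.coords[k] for k in dims},
                       name="relative_warming_slope")
    out.attrs.update({"units": "degC weeks / year", "baseline": baseline_mode,
                      "period": [y0, y1]})
    return out


def detect_bleaching_years(
    median_annual_max: xr.DataArray, threshold: float = 2.0
) -> np.ndarray:
    """Years whose grid-median annual-max DHW reaches the threshold (≥)."""
    vals = median_annual_max.values
    years = median_annual_max["year"].values
    return years[vals >= threshold]


def atmos_change(
    field: xr.DataArray,
    bleaching_years: np.ndarray,
    present: tuple[int, int] = (1999, 2019),
    future: tuple[int, int] = (2050, 2100),
    months=(12, 1, 2, 3),
) -> xr.DataArray:
    """Per-cell % change of an atmospheric field, present → future.

    The field (e.g. wind speed or net shortwave) is averaged over the
    DJFM days of the bleaching-condition austral summers inside each
    window; the result is 100 · (future − present) / present.
    """
    years = np.asarray(bleaching_years)
    pres_years = years[(years >= present[0]) & (years <= present[1])]
    fut_years = years[(years >= future[0]) & (years <= future[1])]
    missing = [name for name, sel in
               (("present", pres_years), ("future", fut_years)) if len(sel) == 0]
    if missing:
        raise ValueError(
            f"no bleaching-condition years fall inside the {missing} window(s)")
    pres = summer_flux_mean(field, years=pres_years, months=months)
    fut = summer_flux_mean(field, years=fut_years, months=months)
    change = 100.0 * (fut - pres) / pres
    change.name = "percent_change"
    change.attrs.update({"units": "%", "present": list(present),
                         "future": list(future),
                         "bleaching_years_present": [int(y) for y in pres_years],
                         "bleaching_years_future": [int(y) for y in fut_years]})
    return change
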