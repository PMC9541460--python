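"""Percentile-based climate-refugia classification and model agreement.

A cell is a (thermal-exposure) refugium if its climatological mean
annual-maximum DHW over 1999–2019 lies in the lowest 20 % of valid
cells: the 20th-percentile value is computed across the grid and every
cell at or below it is flagged. Non-refugia are the remaining valid
cells. Agreement maps count, per cell, how many ensemble members'
refugia masks flag it (0–5 for a five-model ensemble); reference
agreement keeps reference-flagged cells supported by at least
``min_models`` members.
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr

__all__ = [
    "climatological_mean_dhw",
    "classify_refugia",
    "model_agreement",
    "reference_agreement",
    "persistence",
    "PERCENTILE_DEFAULT",
    "PERIOD_DEFAULT",
]

PERCENTILE_DEFAULT = 0.20
PERIOD_DEFAULT = (1999, 2019)


def climatological_mean_dhw(
    annual_max: xr.DataArray, period: tuple[int, int] = PERIOD_DEFAULT
) -> xr.DataArray:
    """Per-cell arithmetic mean of annual-max DHW over the period."""
    y0, y1 = period
    have = set(int(y) for y in annual_max["year"].values)
    missing = [y for y in range(y0, y1 + 1) if y not in have]
    if missing:
        raise ValueError(f"annual-max series missing years {missing}")
    out = annual_max.sel(year=slice(y0, y1)).mean("year")
    out.name = "mean_dhw"
    out.attrs.update({"units": "degC weeks", "period": [y0, y1]})
    return out


def classify_refugia(
    mean_field: xr.DataArray,
    percentile: float = PERCENTILE_DEFAULT,
    domain_mask: xr.DataArray | None = None,
    method: str = "linear",
) -> xr.Dataset:
    """Flag cells at or below the percentile threshold of the mean field.

    The threshold is the ``percentile`` quantile (linear interpolation
    between order statistics by default) of the valid-cell values; ties
    at the threshold are included. If every valid cell has the same
    value, all are flagged and a warning is raised.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    field = mean_field.where(domain_mask) if domain_mask is not None else mean_field
    vals = field.values
    valid = np.isfinite(vals)
    n_valid = int(valid.sum())
    if n_valid < 5:
        raise ValueError(f"need at least 5 valid cells, have {n_valid}")
    pool = vals[valid]
    if np.all(pool == pool[0]):
        warnings.warn("mean-DHW field is constant: every cell qualifies as "
                      "refugium", stacklevel=2)
    threshold = float(np.quantile(pool, percentile, method=method))
    is_ref = valid & (vals <= threshold)
    return xr.Dataset(
        {"is_refugium": (mean_field.dims, is_ref),
         "valid": (mean_field.dims, valid)},
        coords=mean_field.coords,
        attrs={"threshold_value": threshold, "percentile": percentile,
               "quantile_method": method},
    )


def _check_same_grid(masks: list[xr.Dataset]) -> None:
    first = masks[0]["is_refugium"]
    for m in masks[1:]:
        da = m["is_refugium"]
        if da.sizes != first.sizes or any(
            not np.array_equal(da[c].values, first[c].values)
            for c in ("lat", "lon") if c in da.coords
        ):
            raise ValueError("refugia masks are not on a common grid")


def model_agreement(masks: list[xr.Dataset]) -> xr.DataArray:
    """Per-cell count of masks flagging the cell as refugium."""
    if not masks:
        raise ValueError("need at least one mask")
    _check_same_grid(masks)
    count = sum(m["is_refugium"].astype(int) for m in masks)
    count.name = "n_agree"
    count.attrs["n_masks"] = len(masks)
    return count


def reference_agreement(
    masks: list[xr.Dataset], reference: xr.Dataset, min_models: int = 2
) -> xr.DataArray:
    """Reference refugia supported by at least ``min_models`` members."""
    _check_same_grid(list(masks) + [reference])
    n_agree = model_agreement(masks)
    agree = reference["is_refugium"] & (n_agree >= min_models)
    agree.name = "reference_agree"
    agree.attrs["min_models"] = min_models
    return agree


def persistence(
    annual_max: xr.DataArray,
    mask: xr.Dataset,
    percentile: float = PERCENTILE_DEFAULT,
    method: str = "linear",
) -> xr.DataArray:
    """Per-year fraction of refugia cells still below that year's threshold.

    For each year the ``percentile`` quantile of all valid cells' annual
    max DHW is recomputed; the returned series is the fraction of
    classified refugia cells at or below it. Rank-based, so adding a
    spatially uniform offset in any year changes nothing.
    """
    is_ref = mask["is_refugium"].values
    valid = mask["valid"].values if "valid" in mask else np.isfinite(
        annual_max.isel(year=0).values)
    if not is_ref.any():
        raise ValueError("refugia mask is empty")
    fracs = []
    years = annual_max["year"].values
    for y in years:
        vals = annual_max.sel(year=y).values
        pool = vals[valid & np.isfinite(vals)]
        thr = np.quantile(pool, percentile, method=method)
        ref_vals = vals[is_ref]
        fracs.append(float(np.mean(ref_vals <= thr)))
    out = xr.DataArray(np.asarray(fracs), dims=("year",),
                       coords={"year": years}, name="persistence")
    out.attrs["percentile"] = percentile
    return out
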