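import numpy as np
import pandas as pd
import pytest
import xarray as xr

from reefugia.synthetic import GridConfig, generate_forcing, generate_grid


def make_sst(values, start="1985-01-01", lat=None, lon=None):
    """Daily SST DataArray from a (time,) or (time, lat, lon) array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None, None]
    nt, ny, nx = values.shape
    time = pd.date_range(start, periods=nt, freq="D")
    lat = np.asarray(lat) if lat is not None else np.linspace(-19.0, -18.0, ny)
    lon = np.asarray(lon) if lon is not None else np.linspace(145.0, 146.0, nx)
    return xr.DataArray(values, dims=("time", "lat", "lon"),
                        coords={"time": time, "lat": lat, "lon": lon},
                        name="sst")


def days_in(year0, year1):
    return len(pd.date_range(f"{year0}-01-01", f"{year1}-12-31", freq="D"))


def make_annual_max(values, first_year=1999, lat=None, lon=None):
    """Annual-max DHW DataArray from a (year, lat, lon) array."""
    values = np.asarray(values, dtype=float)
    ny_, nyy, nxx = values.shape
    years = np.arange(first_year, first_year + ny_)
    lat = np.asarray(lat) if lat is not None else np.linspace(-19.0, -18.0, nyy)
    lon = np.asarray(lon) if lon is not None else np.linspace(145.0, 146.0, nxx)
    return xr.DataArray(values, dims=("year", "lat", "lon"),
                        coords={"year": years, "lat": lat, "lon": lon},
                        name="annual_max_dhw")


@pytest.fixture(scope="session")
def small_grid_config():
    # ~10 x 12 cells: the smallest domain that keeps >25 valid cells
    return GridConfig(lon_min=145.0, lon_max=146.2, lat_min=-19.0,
                      lat_max=-18.0, resolution=0.1)


@pytest.fixture(scope="session")
def small_grid(small_grid_config):
    return generate_grid(small_grid_config, seed=1)


@pytest.fixture(scope="session")
def small_forcing(small_grid):
    return generate_forcing(small_grid, seed=1, years=(1985, 2020))
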