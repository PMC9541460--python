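"""NetCDF/CSV I/O with provenance attributes.

Gridded data travel as CF-style NetCDF (dimensions time, lat, lon).
Writing prefers whatever engine xarray resolves (the scipy backend's
NetCDF3 classic format suffices for this package's layouts); boolean
variables are stored as int8 flags because classic NetCDF has no
boolean type, and are restored on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__

__all__ = ["save_dataset", "load_dataset", "save_tas", "load_tas", "config_hash"]

_BOOL_FLAG = "reefugia_bool"


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sanitise(obj: xr.Dataset) -> xr.Dataset:
    out = obj.copy()
    for name, var in out.data_vars.items():
        if var.dtype == bool:
            coded = var.astype(np.int8)
            coded.attrs[_BOOL_FLAG] = 1
            out[name] = coded
    # attribute values must be scalars/strings/flat lists for NetCDF3
    for container in [out.attrs] + [v.attrs for v in out.data_vars.values()]:
        for k, v in list(container.items()):
            if v is None:
                container[k] = "none"
            elif isinstance(v, bool):
                container[k] = int(v)
            elif isinstance(v, (tuple, list)):
                container[k] = list(np.asarray(v).ravel())
    return out


def save_dataset(obj: xr.Dataset | xr.DataArray, path, seed=None,
                 config: dict | None = None) -> Path:
    """Write a dataset with software-version / seed / config-hash attrs."""
    path = Path(path)
    ds = obj.to_dataset() if isinstance(obj, xr.DataArray) else obj
    ds = _sanitise(ds)
    ds.attrs["software_version"] = f"reefugia {__version__}"
    if seed is not None:
        ds.attrs["seed"] = seed
    if config is not None:
        ds.attrs["config_hash"] = config_hash(config)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path)
    return path


def load_dataset(path) -> xr.Dataset:
    """Read a dataset written by :func:`save_dataset`, restoring booleans."""
    ds = xr.load_dataset(path)
    for name, var in ds.data_vars.items():
        if var.attrs.pop(_BOOL_FLAG, None):
            ds[name] = var.astype(bool)
    return ds


def save_tas(tas: pd.Series, path) -> Path:
    """Global-mean temperature series as a two-column (year, tas) table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tas.rename_axis("year").to_csv(path, header=["tas"])
    return path


def load_tas(path) -> pd.Series:
    df = pd.read_csv(path, index_col="year")
    return df["tas"]
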