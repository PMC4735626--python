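"""Readers and writers: CF-style NetCDF for gridded stacks, the CPC
plain-text dialect for monthly teleconnection index tables.

NetCDF handling is delegated to xarray; this module only normalizes axis
conventions (ascending latitude, longitude rotated to [-180, 180)) and
moves between xarray objects and the package's stack containers.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec
from .registry import require_variable
from .series import CPC_SENTINEL, TeleconnectionSeries
from .stacks import MonthlyFieldStack

_FILL = 9.969209968386869e36  # CF default float fill


def _to_dataset(stack: MonthlyFieldStack) -> xr.Dataset:
    info = require_variable(stack.variable)
    data = np.where(stack.mask, np.nan, stack.values)
    da = xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={
            "time": stack.times.to_timestamp(how="start"),
            "lat": stack.grid.lat,
            "lon": stack.grid.lon,
        },
        name=stack.variable,
        attrs={"units": stack.units, "long_name": info.long_name},
    )
    da["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    da["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    ds = da.to_dataset()
    ds.attrs["Conventions"] = "CF-1.8"
    return ds


def write_monthly_netcdf(stack: MonthlyFieldStack, path) -> None:
    """Write a stack to CF-style NetCDF (lossless round-trip)."""
    ds = _to_dataset(stack)
    enc = {stack.variable: {"_FillValue": _FILL, "dtype": "float64"}}
    ds.to_netcdf(path, encoding=enc)


def _normalize_axes(da: xr.DataArray) -> xr.DataArray:
    lon = da["lon"].values.astype(float)
    wrapped = ((lon + 180.0) % 360.0) - 180.0
    if not np.array_equal(wrapped, lon):
        da = da.assign_coords(lon=wrapped)
    da = da.sortby("lon")
    if da["lat"].values[0] > da["lat"].values[-1]:
        da = da.sortby("lat")
    return da


def read_monthly_netcdf(path, variable: str) -> MonthlyFieldStack:
    """Read one variable from CF NetCDF into a MonthlyFieldStack.

    Axes are normalized to ascending latitude and longitude in
    [-180, 180); a non-monthly time cadence is rejected.
    """
    require_variable(variable)
    with xr.open_dataset(path, decode_times=True) as ds:
        if variable not in ds:
            raise KeyError(f"variable not found: {variable!r} absent from {path}")
        da = ds[variable].load()
    if set(da.dims) != {"time", "lat", "lon"}:
        da = da.rename({d: n for d, n in zip(da.dims, ("time", "lat", "lon"))})
    da = da.transpose("time", "lat", "lon")
    da = _normalize_axes(da)
    times = pd.DatetimeIndex(da["time"].values).to_period("M")
    steps = np.diff(times.asi8)
    if steps.size and not np.all(steps == 1):
        raise ValueError("cadence error: time axis is not consecutive calendar months")
    values = da.values.astype(float)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    grid = GridSpec(lat=da["lat"].values.astype(float), lon=da["lon"].values.astype(float))
    units = str(da.attrs.get("units", ""))
    return MonthlyFieldStack(variable=variable, units=units, times=times,
                             values=values, grid=grid, mask=mask)


_ROW_RE = re.compile(r"^\s*(-?\d+)[,\s]+(-?\d+)[,\s]+(-?\d+(?:\.\d+)?)\s*$")


def read_index_table(path, name: str = "NAO") -> TeleconnectionSeries:
    """Parse a CPC-dialect monthly index table (year month value rows).

    Values equal to the -99.9 sentinel are masked. Header lines are
    skipped; any other unparseable row raises with its line number.
    """
    periods, vals = [], []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _ROW_RE.match(line)
        if m is None:
            if lineno == 1 and not line.lstrip()[0:1].lstrip("-").isdigit():
                continue  # header
            raise ValueError(f"{path}: unparseable row at line {lineno}: {line!r}")
        year, month, value = int(m.group(1)), int(m.group(2)), float(m.group(3))
        if not 1 <= month <= 12:
            raise ValueError(f"{path}: invalid month {month} at line {lineno}")
        periods.append(pd.Period(f"{year:04d}-{month:02d}", freq="M"))
        vals.append(np.nan if np.isclose(value, CPC_SENTINEL) else value)
    if not periods:
        raise ValueError(f"{path}: no data rows")
    s = pd.Series(vals, index=pd.PeriodIndex(periods, freq="M"))
    return TeleconnectionSeries(name=name, values=s)


def write_index_table(series: TeleconnectionSeries, path) -> None:
    """Write a monthly index series in the CPC text dialect."""
    lines = []
    for p, v in series.values.items():
        out = CPC_SENTINEL if not np.isfinite(v) else v
        lines.append(f"{p.year:5d} {p.month:3d} {out:8.2f}")
    Path(path).write_text("\n".join(lines) + "\n")
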