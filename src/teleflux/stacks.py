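"""Gridded time-stack containers.

``MonthlyFieldStack`` is the universal carrier for monthly fluxes and
climate fields; ``BiweeklyFieldStack`` carries the 24-samples-per-year
vegetation-greenness (NDVI) record. Both hold a plain float array plus a
boolean missing-value mask, a :class:`~teleflux.grid.GridSpec`, and unit
metadata, and validate the cadence invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import GridSpec
from .registry import NDVI, require_variable


def month_index(start: str | pd.Period, n: int) -> pd.PeriodIndex:
    """``n`` consecutive calendar months starting at ``start`` ('YYYY-MM')."""
    return pd.period_range(start=start, periods=n, freq="M")


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    if m.shape != shape:
        raise ValueError("mask shape does not match values")
    return m


@dataclass
class MonthlyFieldStack:
    """A (time, lat, lon) stack of one variable on consecutive months."""

    variable: str
    units: str
    times: pd.PeriodIndex  # monthly, strictly consecutive
    values: np.ndarray  # (nt, nlat, nlon)
    grid: GridSpec
    mask: np.ndarray | None = None  # True = missing

    def __post_init__(self):
        require_variable(self.variable)
        self.values = np.asarray(self.values, dtype=float)
        if not isinstance(self.times, pd.PeriodIndex) or self.times.freqstr not in ("M", "ME"):
            raise ValueError("times must be a monthly PeriodIndex")
        if len(self.times) == 0:
            raise ValueError("empty stack: time axis has no months")
        steps = np.diff(self.times.asi8)
        if steps.size and not np.all(steps == 1):
            raise ValueError("cadence error: times must be strictly consecutive months")
        nt = len(self.times)
        if self.values.shape != (nt,) + self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != (time, lat, lon) "
                f"{(nt,) + self.grid.shape}"
            )
        self.mask = _as_mask(self.mask, self.values.shape)
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("values must be finite where unmasked")

    @property
    def shape(self):
        return self.values.shape

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.times.year)

    def sel_months(self, months) -> np.ndarray:
        """Boolean time selector for a set of calendar months (1-12)."""
        return np.isin(self.times.month, list(months))

    def copy_with(self, **kw) -> "MonthlyFieldStack":
        out = replace(self, **kw)
        return out


@dataclass
class BiweeklyFieldStack:
    """NDVI at 24 samples per covered year; values in [-1, 1] where unmasked."""

    years: np.ndarray  # consecutive calendar years
    values: np.ndarray  # (n_years, 24, nlat, nlon)
    grid: GridSpec
    units: str = "1"
    variable: str = field(default=NDVI.name)
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.variable != NDVI.name:
            raise ValueError("BiweeklyFieldStack carries NDVI only")
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.years.size == 0:
            raise ValueError("empty stack: no years")
        if self.years.size > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be consecutive")
        expect = (self.years.size, 24) + self.grid.shape
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != {expect}")
        self.mask = _as_mask(self.mask, self.values.shape)
        v = self.values[~self.mask]
        if v.size and (np.nanmin(v) < -1 - 1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("NDVI values must lie in [-1, 1] where unmasked")
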