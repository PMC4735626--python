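"""Deseasonalization, annual/seasonal integration and regional aggregation.

The anomaly convention follows the standard flux-analysis recipe: a
per-pixel, per-calendar-month climatology over a base period is removed
from the monthly stack; annual anomalies are the *sum* of the twelve
monthly anomalies (flux month^-1 integrates to flux yr^-1), seasonal
diagnostics are window means (Dec-Apr attributes December to the
following year's winter; May-Sep is within-year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RegionMask, area_weights, cell_areas
from .stacks import BiweeklyFieldStack, MonthlyFieldStack

WINDOWS = {
    "DecApr": ((-1, 12), (0, 1), (0, 2), (0, 3), (0, 4)),  # (year offset, month)
    "MaySep": ((0, 5), (0, 6), (0, 7), (0, 8), (0, 9)),
}


@dataclass
class ClimatologyField:
    """Per-calendar-month mean fields over a base period (12 layers)."""

    variable: str
    values: np.ndarray  # (12, nlat, nlon)
    base_period: tuple[int, int]  # (first_year, last_year), inclusive

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 12:
            raise ValueError("climatology must have exactly 12 monthly layers")


@dataclass
class AnomalyStack:
    """A deseasonalized monthly stack plus the climatology removed from it."""

    stack: MonthlyFieldStack
    climatology: ClimatologyField

    def __getattr__(self, item):
        return getattr(self.stack, item)


def deseasonalize(stack: MonthlyFieldStack,
                  base_period: tuple[int, int] | None = None) -> AnomalyStack:
    """Remove the per-pixel mean seasonal cycle estimated over ``base_period``.

    ``base_period`` defaults to the full span of the stack. Every calendar
    month must occur at least twice within the base period.
    """
    years = stack.times.year
    if base_period is None:
        base_period = (int(years.min()), int(years.max()))
    y0, y1 = base_period
    in_base = (years >= y0) & (years <= y1)
    months = stack.times.month
    clim = np.empty((12,) + stack.grid.shape)
    valid = ~stack.mask
    for m in range(1, 13):
        sel = in_base & (months == m) & np.any(valid, axis=(1, 2))
        if sel.sum() < 2:
            raise ValueError(
                f"month {m} occurs fewer than 2 times in base period {base_period}"
            )
        v = stack.values[sel]
        w = valid[sel].astype(float)
        cnt = w.sum(axis=0)
        with np.errstate(invalid="ignore"):
            clim[m - 1] = np.where(cnt > 0, (v * w).sum(axis=0) / np.where(cnt == 0, 1, cnt), np.nan)
    anoms = stack.values - clim[months - 1]
    anoms = np.where(stack.mask, 0.0, anoms)
    out = stack.copy_with(values=anoms, mask=stack.mask.copy())
    return AnomalyStack(stack=out,
                        climatology=ClimatologyField(stack.variable, clim, base_period))


def _year_month_slice(times: pd.PeriodIndex, year: int, month: int) -> int:
    loc = np.flatnonzero((times.year == year) & (times.month == month))
    if loc.size != 1:
        raise ValueError(f"incomplete year: month {year}-{month:02d} missing")
    return int(loc[0])


def annual_integral(anoms: AnomalyStack, year: int) -> np.ndarray:
    """Per-pixel sum of the 12 monthly anomalies of ``year`` (-> per yr)."""
    idx = [_year_month_slice(anoms.times, year, m) for m in range(1, 13)]
    return anoms.values[idx].sum(axis=0)


def seasonal_window_mean(anoms: AnomalyStack, window: str, year: int) -> np.ndarray:
    """Per-pixel mean anomaly over a 5-month window attributed to ``year``.

    ``DecApr`` takes December from ``year - 1``; ``MaySep`` is May-Sep of
    ``year`` itself.
    """
    try:
        spec = WINDOWS[window]
    except KeyError:
        raise ValueError(f"unknown window {window!r}; use one of {sorted(WINDOWS)}") from None
    try:
        idx = [_year_month_slice(anoms.times, year + dy, m) for dy, m in spec]
    except ValueError:
        raise ValueError(f"incomplete window {window} for year {year}") from None
    return anoms.values[idx].mean(axis=0)


def regional_integrate(field: np.ndarray, mask: RegionMask, mode: str = "integral",
                       per_cell: bool = True) -> float:
    """Aggregate a 2-d field over a region.

    ``integral`` sums value * weight (times cell area when values are
    per-area densities, ``per_cell=False``); ``mean`` returns the
    area-weighted regional mean for intensive variables.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != mask.grid.shape:
        raise ValueError("field and mask are on different grids")
    w = mask.weights
    if not np.any(w > 0):
        raise ValueError("empty region")
    if mode == "integral":
        if per_cell:
            return float((field * w).sum())
        return float((field * w * cell_areas(mask.grid)).sum())
    if mode == "mean":
        aw = area_weights(mask.grid) * w
        return float((field * aw).sum() / aw.sum())
    raise ValueError(f"unknown mode {mode!r}")


def annual_regional_series(anoms: AnomalyStack, mask: RegionMask, dataset: str,
                           mode: str = "integral", per_cell: bool = True):
    """AnnualAnomalySeries of yearly integrals over complete years only."""
    from .series import AnnualAnomalySeries

    counts = pd.Series(1, index=anoms.times).groupby(anoms.times.year).sum()
    years = [int(y) for y, c in counts.items() if c == 12]
    vals = {}
    for y in years:
        f = annual_integral(anoms, y)
        vals[y] = regional_integrate(f, mask, mode=mode, per_cell=per_cell)
    units = anoms.units.replace("month-1", "yr-1") if mode == "integral" else anoms.units
    return AnnualAnomalySeries(dataset=dataset, region=mask.name,
                               values=pd.Series(vals), units=units)


def integrate_ndvi_annual(ndvi: BiweeklyFieldStack) -> tuple[np.ndarray, np.ndarray]:
    """Annual greenness-integral anomalies from biweekly NDVI.

    Returns ``(years, anomalies)`` where anomalies has shape
    (n_years, nlat, nlon): per-pixel sum of the 24 biweekly samples of
    each year, minus the multi-year mean of those sums. Biweekly samples
    are equally weighted.
    """
    # pixels masked for the whole record are tolerated (ocean); a year
    # with some but not all samples missing at a pixel is incomplete
    partially_missing = ndvi.mask.any(axis=1) & ~ndvi.mask.all(axis=(0, 1))[None, :, :]
    if partially_missing.any():
        raise ValueError("incomplete year: some biweekly samples are missing")
    integrals = ndvi.values.sum(axis=1)  # (n_years, nlat, nlon)
    anomalies = integrals - integrals.mean(axis=0, keepdims=True)
    return ndvi.years.copy(), anomalies


def pdsi_regional_departure(pdsi: MonthlyFieldStack, mask: RegionMask) -> pd.Series:
    """Monthly regional-mean PDSI minus its full-period time mean.

    The drought diagnostic used when an index has a strong regional
    baseline: departures isolate the temporal drought signal.
    """
    aw = area_weights(mask.grid) * mask.weights
    if not np.any(aw > 0):
        raise ValueError("empty region")
    regional = (pdsi.values * aw).sum(axis=(1, 2)) / aw.sum()
    departures = regional - regional.mean()
    return pd.Series(departures, index=pdsi.times)
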