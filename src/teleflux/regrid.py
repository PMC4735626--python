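"""Remapping between regular lat/lon grids.

Flux variables are remapped first-order conservatively (area-weighted
interval overlaps, separable in lat and lon on regular grids) so that
PgC area integrals are preserved; intensive variables are remapped
bilinearly, which reproduces constants exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grid import GridSpec, cell_areas
from .registry import is_flux
from .stacks import MonthlyFieldStack


def _overlap_matrix(src_b: np.ndarray, tgt_b: np.ndarray, sin_measure: bool) -> np.ndarray:
    """(n_tgt, n_src) matrix of interval-overlap measures along one axis.

    Latitude uses the sin-lat measure (exact spherical area), longitude
    plain length; together they give exact cell-area overlaps.
    """
    lo = np.maximum(tgt_b[:-1, None], src_b[None, :-1])
    hi = np.minimum(tgt_b[1:, None], src_b[None, 1:])
    hi = np.maximum(hi, lo)
    if sin_measure:
        return np.sin(np.deg2rad(hi)) - np.sin(np.deg2rad(lo))
    return hi - lo


def _conservative(values: np.ndarray, mask: np.ndarray,
                  src: GridSpec, tgt: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted average of source densities over each target cell."""
    A = _overlap_matrix(src.lat_bounds(), tgt.lat_bounds(), True)  # (nlat_t, nlat_s)
    B = _overlap_matrix(src.lon_bounds(), tgt.lon_bounds(), False)
    if A.sum() == 0 or B.sum() == 0:
        raise ValueError("no overlap between source and target grids")
    valid = (~mask).astype(float)
    v = np.where(mask, 0.0, values)
    # numerator / denominator via two separable tensor contractions
    num = np.einsum("ij,tjk,lk->til", A, v * valid, B, optimize=True)
    den = np.einsum("ij,tjk,lk->til", A, valid, B, optimize=True)
    out_mask = den <= 1e-12 * A.max() * B.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_mask, 0.0, num / np.where(den == 0, 1.0, den))
    return out, out_mask


def _bilinear(values: np.ndarray, mask: np.ndarray,
              src: GridSpec, tgt: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    pts_lat, pts_lon = np.meshgrid(tgt.lat, tgt.lon, indexing="ij")
    query = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])
    nt = values.shape[0]
    out = np.empty((nt,) + tgt.shape)
    out_mask = np.zeros((nt,) + tgt.shape, dtype=bool)
    for t in range(nt):
        v = np.where(mask[t], np.nan, values[t])
        itp = RegularGridInterpolator((src.lat, src.lon), v, method="linear",
                                      bounds_error=False, fill_value=np.nan)
        res = itp(query).reshape(tgt.shape)
        bad = ~np.isfinite(res)
        out[t] = np.where(bad, 0.0, res)
        out_mask[t] = bad
    return out, out_mask


def regrid_to_common(stack: MonthlyFieldStack, target: GridSpec) -> MonthlyFieldStack:
    """Remap a stack to ``target``; conservative for fluxes, bilinear else.

    Per-cell flux units (containing "cell") are converted to densities
    before the conservative remap and back after it, so the area
    integral over the common domain is conserved.
    """
    if (target.lat[0] > stack.grid.lat[-1] or target.lat[-1] < stack.grid.lat[0]
            or target.lon[0] > stack.grid.lon[-1] or target.lon[-1] < stack.grid.lon[0]):
        raise ValueError("no overlap between source and target domains")
    if is_flux(stack.variable):
        per_cell = "cell" in stack.units
        v = stack.values
        if per_cell:
            v = v / cell_areas(stack.grid)[None, :, :]
        out, out_mask = _conservative(v, stack.mask, stack.grid, target)
        if per_cell:
            out = out * cell_areas(target)[None, :, :]
    else:
        out, out_mask = _bilinear(stack.values, stack.mask, stack.grid, target)
    return MonthlyFieldStack(variable=stack.variable, units=stack.units,
                             times=stack.times, values=out, grid=target,
                             mask=out_mask)
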