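"""PCA/EOF analysis of annual NBP anomaly fields.

Annual anomaly fields (year x lat x lon), already resampled to a common
grid, are decomposed by an area-weighted PCA over the spatial dimension:
anomalies are scaled by sqrt(cos lat) before the SVD so that the
variance being partitioned is the area-weighted spatio-temporal
variance. The leading EOF of the European NBP field is, for every
dataset the analysis targets, a dipole whose centres of action identify
the regions driving continental sink variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec


@dataclass
class EOFResult:
    """Leading mode of a field PCA: pattern, amplitudes, variance share."""

    eof1: np.ndarray  # (nlat, nlon), NaN where masked
    pc1: pd.Series  # year -> amplitude
    explained_variance: float  # fraction in (0, 1]
    explained_all: np.ndarray  # all computed modes' fractions
    grid: GridSpec
    centers: list[tuple[float, float, int]] | None = None  # (lat, lon, sign)
    dipolar: bool = True


class FieldPCA:
    """Area-weighted PCA of annual anomaly fields on a common grid.

    Cells masked in *any* year are excluded consistently from the
    decomposition; PC1 is oriented to correlate positively with the
    domain-integral series so its positive phase means a stronger
    continental sink.
    """

    def __init__(self, years, fields: np.ndarray, grid: GridSpec,
                 mask: np.ndarray | None = None):
        fields = np.asarray(fields, dtype=float)
        self.years = np.asarray(years, dtype=int)
        if fields.ndim != 3 or fields.shape[0] != self.years.size:
            raise ValueError("fields must be (n_years, nlat, nlon)")
        if fields.shape[0] < 3:
            raise ValueError("need at least 3 years for a field PCA")
        if fields.shape[1:] != grid.shape:
            raise ValueError("fields do not match the grid")
        self.grid = grid
        cell_bad = ~np.isfinite(fields).all(axis=0)
        if mask is not None:
            cell_bad |= np.asarray(mask, dtype=bool).any(axis=0) if mask.ndim == 3 \
                else np.asarray(mask, dtype=bool)
        self.valid = ~cell_bad
        if not self.valid.any():
            raise ValueError("all cells masked: nothing to decompose")
        self.fields = np.where(cell_bad[None], 0.0, fields)

    def _weights(self) -> np.ndarray:
        return np.sqrt(np.cos(np.deg2rad(self.grid.lat)))[:, None] * np.ones(
            (1, self.grid.lon.size))

    def reconstruct(self) -> np.ndarray:
        """Rebuild the anomaly fields from the full mode expansion.

        Returns fields identical to the (mean-removed) input up to
        numerical precision — the completeness check of the expansion.
        """
        w = self._weights()
        X = (self.fields * w[None])[:, self.valid]
        Xc = X - X.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        rebuilt = (u * s) @ vt
        out = np.zeros_like(self.fields)
        out[:, self.valid] = rebuilt / w[self.valid][None]
        return out

    def fit(self, n_modes: int | None = None) -> EOFResult:
        w = self._weights()
        X = (self.fields * w[None])[:, self.valid]  # (ny, n_valid)
        Xc = X - X.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        frac = s**2 / np.sum(s**2)
        k = s.size if n_modes is None else min(n_modes, s.size)
        pc1 = u[:, 0] * s[0]
        # sign: positive PC1 = stronger domain-integrated sink
        integral = self.fields.sum(axis=(1, 2))
        if np.corrcoef(pc1, integral)[0, 1] < 0:
            pc1 = -pc1
            vt = vt.copy()
            vt[0] = -vt[0]
        eof1 = np.full(self.grid.shape, np.nan)
        eof1[self.valid] = vt[0] / w[self.valid]  # unweighted pattern, unit weighted norm
        return EOFResult(
            eof1=eof1,
            pc1=pd.Series(pc1, index=self.years),
            explained_variance=float(frac[0]),
            explained_all=frac[:k],
            grid=self.grid,
        )


def nbp_pca(years, fields: np.ndarray, grid: GridSpec,
            mask: np.ndarray | None = None) -> EOFResult:
    """Leading EOF/PC of annual NBP anomaly fields with centres attached."""
    res = FieldPCA(years, fields, grid, mask=mask).fit()
    try:
        res.centers, res.dipolar = centers_of_action(res.eof1, grid)
    except ValueError:
        res.centers, res.dipolar = None, False
    return res


def _local_mean(f: np.ndarray, radius: int) -> np.ndarray:
    """Center-weighted neighborhood average ignoring NaNs.

    The kernel weight 2^-(di^2+dj^2) decays away from the center, so a
    single-cell extremum keeps its own cell as the smoothed maximum
    (no plateau ties) while pixel noise is still averaged down.
    """
    vals = np.where(np.isfinite(f), f, 0.0)
    cnt = np.isfinite(f).astype(float)
    num = np.zeros_like(vals)
    den = np.zeros_like(vals)
    n_i, n_j = f.shape
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            w = 2.0 ** (-(di * di + dj * dj))
            i0, i1 = max(di, 0), min(n_i + di, n_i)
            j0, j1 = max(dj, 0), min(n_j + dj, n_j)
            num[i0 - di:i1 - di, j0 - dj:j1 - dj] += w * vals[i0:i1, j0:j1]
            den[i0 - di:i1 - di, j0 - dj:j1 - dj] += w * cnt[i0:i1, j0:j1]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den == 0, 1, den), np.nan)
    return out


def centers_of_action(eof1: np.ndarray, grid: GridSpec,
                      smooth: int = 1) -> tuple[list[tuple[float, float, int]], bool]:
    """Locate the two extremal loadings of a (dipolar) EOF pattern.

    Extrema are found on a locally averaged map ((2*smooth+1)^2 window;
    ``smooth=0`` disables it) so single-pixel noise does not displace a
    centre off its lobe. Returns ``([(lat, lon, sign), (lat, lon,
    sign)], dipolar)`` for the maximum and minimum loading; if both
    extrema share a sign the pattern is flagged non-dipolar.
    """
    raw = np.asarray(eof1, dtype=float)
    finite = np.isfinite(raw)
    if not finite.any() or np.nanmax(raw) == np.nanmin(raw):
        raise ValueError("no centers: constant or empty loading map")
    f = _local_mean(raw, smooth) if smooth > 0 else raw
    imax = np.unravel_index(np.nanargmax(f), f.shape)
    imin = np.unravel_index(np.nanargmin(f), f.shape)
    centers = [
        (float(grid.lat[imax[0]]), float(grid.lon[imax[1]]), 1),
        (float(grid.lat[imin[0]]), float(grid.lon[imin[1]]), -1),
    ]
    dipolar = (f[imax] > 0) and (f[imin] < 0)
    return centers, dipolar


def regional_variance_share(regional: pd.Series, continental: pd.Series) -> float:
    """Percent of continental-series variance associated with a region.

    Computed as the squared Pearson correlation of the two annual
    series over their common years, in percent.
    """
    common = regional.index.intersection(continental.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common years")
    x = regional.loc[common].to_numpy(dtype=float)
    y = continental.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input series")
    r = np.corrcoef(x, y)[0, 1]
    return float(100.0 * r * r)
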