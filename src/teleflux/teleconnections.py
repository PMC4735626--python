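"""Circulation modes and NAO-EA phase classification.

Two fit-style entry points live here:

* :class:`RotatedPCA` — varimax-rotated principal component analysis of
  standardized monthly z500 anomalies over a North-Atlantic window,
  yielding NAO- and EA-like modes with standardized amplitude series
  (the procedure behind operational teleconnection indices);
* the tercile machinery — DJF winter means of monthly indices,
  classification of each winter into +, - or neutral phase per index,
  and the joint five-way composite labelling used throughout the
  downstream flux analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, RegionBox
from .series import TeleconnectionSeries, WinterIndexSeries
from .stacks import MonthlyFieldStack

COMPOSITES = ("NAO+EA+", "NAO-EA-", "NAO+EA-", "NAO-EA+", "neutral")
ANTIPHASE = ("NAO+EA-", "NAO-EA+")


# ---------------------------------------------------------------------------
# Winter indices and phase classification
# ---------------------------------------------------------------------------

def winter_index(series: TeleconnectionSeries) -> WinterIndexSeries:
    """DJF mean per winter; winter ``y`` = mean of Dec(y-1), Jan(y), Feb(y).

    A winter is reported only if at least two of its three months are
    unmasked; the mean is taken over the unmasked months.
    """
    s = series.values
    years = np.unique([p.year for p in s.index])
    out = {}
    for y in range(int(years.min()), int(years.max()) + 2):
        months = [
            series.month_value(y - 1, 12),
            series.month_value(y, 1),
            series.month_value(y, 2),
        ]
        arr = np.asarray(months, dtype=float)
        covered = [
            pd.Period(f"{y - 1}-12", freq="M") in s.index,
            pd.Period(f"{y}-01", freq="M") in s.index,
            pd.Period(f"{y}-02", freq="M") in s.index,
        ]
        if sum(covered) < 2:
            continue  # winter not spanned by the record
        n_ok = int(np.isfinite(arr).sum())
        out[y] = float(np.nanmean(arr)) if n_ok >= 2 else np.nan
    if not out:
        raise ValueError("series does not span any DJF winter")
    return WinterIndexSeries(name=series.name, values=pd.Series(out))


def empirical_terciles(values: np.ndarray) -> tuple[float, float]:
    """Lower/upper terciles by linear interpolation of order statistics."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    lo, hi = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    return float(lo), float(hi)


@dataclass
class PhaseAssignment:
    """Per-winter NAO/EA phases and the joint composite label.

    A winter is assigned to one of the four non-neutral composites only
    when *both* indices exceed a tercile; any other winter is neutral.
    Tercile thresholds (lower, upper) per index are recorded.
    """

    table: pd.DataFrame  # index winter_year; columns nao, ea, nao_phase, ea_phase, composite
    thresholds: dict[str, tuple[float, float]]

    def __post_init__(self):
        need = {"nao", "ea", "nao_phase", "ea_phase", "composite"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"assignment table missing columns {need - set(self.table.columns)}")
        for name, (lo, hi) in self.thresholds.items():
            if not lo < hi:
                raise ValueError(f"{name}: lower tercile must be < upper tercile")

    @property
    def years(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def composite_of(self, year: int) -> str:
        return str(self.table.loc[year, "composite"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "winter_year"
        out.to_csv(path)


def _phase(value: float, lo: float, hi: float) -> str:
    if not np.isfinite(value):
        return "0"
    if value > hi:
        return "+"
    if value < lo:
        return "-"
    return "0"


def classify_phases(nao: WinterIndexSeries, ea: WinterIndexSeries,
                    base_period: tuple[int, int] | None = None) -> PhaseAssignment:
    """Tercile phase classification of each winter and joint labelling.

    Terciles are computed per index over ``base_period`` (default: all
    common winters). Exceedance is strict: a value exactly at a tercile
    is neutral. The joint composite is non-neutral iff both single-index
    phases are.
    """
    common = nao.values.index.intersection(ea.values.index)
    if base_period is None:
        base_period = (int(common.min()), int(common.max()))
    y0, y1 = base_period
    base = [y for y in common if y0 <= y <= y1]
    if len(base) < 9:
        raise ValueError("too short for terciles: base period has "
                         f"{len(base)} winters (< 9)")
    thresholds = {
        "NAO": empirical_terciles(nao.values.loc[base].to_numpy()),
        "EA": empirical_terciles(ea.values.loc[base].to_numpy()),
    }
    rows = {}
    for y in common:
        nv, ev = float(nao.values[y]), float(ea.values[y])
        np_, ep = _phase(nv, *thresholds["NAO"]), _phase(ev, *thresholds["EA"])
        if np_ != "0" and ep != "0":
            comp = f"NAO{np_}EA{ep}"
        else:
            comp = "neutral"
        rows[y] = (nv, ev, np_, ep, comp)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["nao", "ea", "nao_phase", "ea_phase", "composite"]
    ).sort_index()
    return PhaseAssignment(table=table, thresholds=thresholds)


def composite_membership(assignment: PhaseAssignment) -> dict[str, list[int]]:
    """Five disjoint, exhaustive ordered year lists, one per composite."""
    out: dict[str, list[int]] = {c: [] for c in COMPOSITES}
    for y in sorted(assignment.years):
        out[assignment.composite_of(int(y))].append(int(y))
    return out


def longest_antiphase_run(assignment: PhaseAssignment) -> tuple[int, int]:
    """Longest consecutive run of anti-phase winters (NAO+EA- or NAO-EA+).

    Returns ``(start_year, length)``; ties go to the earliest start.
    A run must be consecutive in calendar years.
    """
    years = sorted(int(y) for y in assignment.years)
    best = (years[0], 0)
    cur_start, cur_len = None, 0
    prev_year = None
    for y in years:
        anti = assignment.composite_of(y) in ANTIPHASE
        contiguous = prev_year is not None and y == prev_year + 1
        if anti:
            if cur_len > 0 and contiguous:
                cur_len += 1
            else:
                cur_start, cur_len = y, 1
            if cur_len > best[1]:
                best = (cur_start, cur_len)
        else:
            cur_len = 0
        prev_year = y
    return best


# ---------------------------------------------------------------------------
# Rotated PCA of z500
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a (p, k) loading matrix.

    Maximizes the raw varimax simplicity criterion
    ``sum_j [ mean(L^4) - mean(L^2)^2 ]`` without Kaiser normalization,
    by the classic SVD-based alternating algorithm.
    """
    p, k = loadings.shape
    R = np.eye(k)
    if k < 2:
        return R
    d = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - L * (np.sum(L**2, axis=0) / p))
        )
        R = u @ vt
        d_new = float(np.sum(s))
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return R


def varimax_simplicity(loadings: np.ndarray) -> float:
    """The raw varimax criterion value of a loading matrix."""
    L2 = loadings**2
    return float(np.sum(L2.var(axis=0)))


def congruence(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Tucker congruence coefficient between two flattened patterns."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float).ravel()
    num = np.sum(w * a * b)
    den = np.sqrt(np.sum(w * a * a) * np.sum(w * b * b))
    return float(num / den) if den > 0 else 0.0


@dataclass
class RotatedPCAResults:
    """Varimax-rotated modes of a standardized anomaly field.

    ``loadings`` are spatial patterns on the analysis subgrid (mode,
    lat, lon); ``amplitudes`` are the standardized monthly series, one
    column per mode; ``explained_variance`` fractions refer to the
    *unrotated* leading modes (non-increasing); ``rotated_variance``
    holds the per-mode variance shares after rotation.
    """

    loadings: np.ndarray
    amplitudes: pd.DataFrame
    explained_variance: np.ndarray
    rotated_variance: np.ndarray
    grid: GridSpec
    rotation: str = "varimax"
    domain_name: str = ""

    @property
    def n_modes(self) -> int:
        return self.loadings.shape[0]

    def amplitude_series(self, mode: int, name: str) -> TeleconnectionSeries:
        s = self.amplitudes.iloc[:, mode]
        return TeleconnectionSeries(name=name, values=s)

    def match_modes(self, references: dict[str, np.ndarray],
                    weights: np.ndarray | None = None) -> dict[str, int]:
        """Match mode indices to named reference patterns by |congruence|.

        Greedy over decreasing |congruence|; rotation does not preserve
        variance ordering, so naming must go through pattern matching.
        """
        pairs = []
        for name, ref in references.items():
            for m in range(self.n_modes):
                c = abs(congruence(self.loadings[m], ref, weights))
                pairs.append((c, name, m))
        pairs.sort(reverse=True)
        out: dict[str, int] = {}
        used: set[int] = set()
        for c, name, m in pairs:
            if name in out or m in used:
                continue
            out[name] = m
            used.add(m)
        return out

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": np.arange(self.n_modes),
            "explained_variance_unrotated": self.explained_variance[: self.n_modes],
            "variance_share_rotated": self.rotated_variance,
        })


class RotatedPCA:
    """Rotated PCA of monthly z500 anomalies over a lat/lon window.

    Parameters
    ----------
    z500
        Monthly geopotential-height stack covering the analysis domain.
    domain
        Analysis window (e.g. the North-Atlantic sector 20-80N, 90W-50E).
    months
        Calendar months entering the analysis (default DJF).
    base_period
        Years over which the per-pixel, per-calendar-month
        standardization is computed (default: full span).

    ``fit(n_retain)`` standardizes anomalies per pixel and calendar
    month, applies sqrt(cos-lat) area weighting, extracts the leading
    ``n_retain`` principal components and varimax-rotates them;
    amplitude series are re-standardized to unit variance. Mode signs
    follow the meteorological convention that the positive phase has
    *negative* height anomalies at the northern center of action.
    """

    def __init__(self, z500: MonthlyFieldStack, domain: RegionBox,
                 months=(12, 1, 2), base_period: tuple[int, int] | None = None):
        if z500.variable != "Z500":
            raise ValueError("RotatedPCA expects a Z500 stack")
        self.domain = domain
        self.months = tuple(months)
        lat_in = (z500.grid.lat >= domain.lat_min) & (z500.grid.lat <= domain.lat_max)
        lon_in = (z500.grid.lon >= domain.lon_min) & (z500.grid.lon <= domain.lon_max)
        if not lat_in.any() or not lon_in.any():
            raise ValueError("no overlap between stack grid and analysis domain")
        self.grid = GridSpec(lat=z500.grid.lat[lat_in], lon=z500.grid.lon[lon_in])
        sel_t = z500.sel_months(self.months)
        n_years_cover = len(np.unique(z500.times[sel_t].year))
        if n_years_cover < 10:
            raise ValueError("need at least 10 years of the selected months")
        self.times = z500.times[sel_t]
        v = z500.values[np.ix_(sel_t, np.flatnonzero(lat_in), np.flatnonzero(lon_in))]
        self.values = v
        years = self.times.year
        self.base_period = (
            (int(years.min()), int(years.max())) if base_period is None else base_period
        )

    def _standardize(self) -> np.ndarray:
        months = self.times.month
        years = self.times.year
        y0, y1 = self.base_period
        in_base = (years >= y0) & (years <= y1)
        z = np.empty_like(self.values)
        for m in self.months:
            sel = months == m
            base = sel & in_base
            if base.sum() < 2:
                raise ValueError(f"fewer than 2 occurrences of month {m} in base period")
            mu = self.values[base].mean(axis=0)
            sd = self.values[base].std(axis=0, ddof=1)
            sd = np.where(sd <= 0, 1.0, sd)
            z[sel] = (self.values[sel] - mu) / sd
        return z

    def fit(self, n_retain: int = 10) -> RotatedPCAResults:
        z = self._standardize()
        nt = z.shape[0]
        nlat, nlon = self.grid.shape
        w = np.sqrt(np.cos(np.deg2rad(self.grid.lat)))[:, None] * np.ones((1, nlon))
        X = (z * w[None]).reshape(nt, nlat * nlon)
        X = X - X.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        total_var = float(np.sum(s**2))
        n_avail = int(np.sum(s > 1e-12 * s[0]))
        if n_retain > n_avail:
            raise ValueError(f"n_retain={n_retain} exceeds available modes ({n_avail})")
        explained = (s**2) / total_var
        # loadings scaled by singular values: covariance-style loadings
        L = (vt[:n_retain].T * s[:n_retain]) / np.sqrt(nt - 1)
        R = varimax(L)
        Lr = L @ R
        amps = u[:, :n_retain] @ R  # orthonormal columns
        rot_var = (Lr**2).sum(axis=0) / (total_var / (nt - 1))
        # sign convention: dominant extremum in the northern half negative
        north = self.grid.lat >= self.grid.lat.mean()
        maps = Lr.T.reshape(n_retain, nlat, nlon)
        for k in range(n_retain):
            sub = maps[k][north]
            peak = sub.ravel()[np.argmax(np.abs(sub))]
            if peak > 0:
                maps[k] = -maps[k]
                amps[:, k] = -amps[:, k]
        # unweight the loading maps for interpretability
        with np.errstate(invalid="ignore", divide="ignore"):
            maps = maps / w[None]
        amps = amps / amps.std(axis=0, ddof=1, keepdims=True)
        amp_df = pd.DataFrame(amps, index=self.times,
                              columns=[f"mode{k}" for k in range(n_retain)])
        return RotatedPCAResults(
            loadings=maps,
            amplitudes=amp_df,
            explained_variance=explained,
            rotated_variance=rot_var,
            grid=self.grid,
            domain_name=self.domain.name,
        )


def compute_rotated_modes(z500: MonthlyFieldStack, domain: RegionBox,
                          months=(12, 1, 2), n_retain: int = 10,
                          base_period: tuple[int, int] | None = None) -> RotatedPCAResults:
    """Functional wrapper: ``RotatedPCA(...).fit(n_retain)``."""
    return RotatedPCA(z500, domain, months=months, base_period=base_period).fit(n_retain)
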