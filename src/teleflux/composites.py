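"""Phase-composite statistics of flux and climate anomalies.

The central object is :class:`PhaseCompositeModel`: annual, regionally
integrated anomaly series from several datasets (inversions and
vegetation models as two groups), together with a winter phase
assignment, fitted to composite means with ANOVA significance.

Terminology used by its results:

* the *one-sided* test of a composite is the F-test of its mean against
  zero, F = t^2 with p from F(1, n-1) — the test of "is the average
  anomaly in this phase combination nonzero";
* the *two-sided* test of a composite pair is the ordinary one-way
  two-group ANOVA for equality of the two composite means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .anomaly import AnomalyStack, seasonal_window_mean
from .grid import RegionMask
from .series import AnnualAnomalySeries
from .teleconnections import COMPOSITES, PhaseAssignment, composite_membership


# ---------------------------------------------------------------------------
# Elementary composite statistics
# ---------------------------------------------------------------------------

def composite_mean(series: AnnualAnomalySeries,
                   membership: dict[str, list[int]]) -> dict[str, tuple[float, int]]:
    """Mean anomaly of the member years of each composite, with count.

    Years missing from the series (shorter archives) are dropped; an
    empty composite is reported as (nan, 0).
    """
    out = {}
    for comp, years in membership.items():
        have = [y for y in years if y in series.values.index]
        if have:
            out[comp] = (float(series.values.loc[have].mean()), len(have))
        else:
            out[comp] = (float("nan"), 0)
    return out


@dataclass
class CompositeStats:
    """One composite's pooled statistics within one dataset group."""

    composite: str
    region: str
    group: str
    n_years: int
    mean: float
    sd: float
    F: float
    p: float
    degenerate: str = ""

    def as_row(self) -> dict:
        return {
            "composite": self.composite, "region": self.region, "group": self.group,
            "n": self.n_years, "mean": self.mean, "sd": self.sd,
            "F": self.F, "p": self.p, "flag": self.degenerate,
        }


def composite_significance(values, composite: str = "", region: str = "",
                           group: str = "") -> CompositeStats:
    """F-test of a composite-mean anomaly against zero (F = t^2).

    ``values`` are the member-year anomalies pooled across the datasets
    of one group. Zero-variance input with nonzero mean is flagged
    degenerate (p reported as 0).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        raise ValueError("insufficient years: need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return CompositeStats(composite, region, group, n, mean, sd, 0.0, 1.0)
        return CompositeStats(composite, region, group, n, mean, sd, np.inf, 0.0,
                              degenerate="degenerate: zero variance")
    t = mean / (sd / np.sqrt(n))
    F = t * t
    p = float(stats.f.sf(F, 1, n - 1))
    return CompositeStats(composite, region, group, n, mean, sd, float(F), p)


def composite_pairwise_difference(values_a, values_b) -> tuple[float, float, str]:
    """Two-group one-way ANOVA F and p for equality of composite means.

    Equal-variance pooling, so F equals the squared pooled two-sample t.
    Returns (F, p, flag); zero within-group variance with distinct
    means is flagged degenerate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("insufficient group size: need at least 2 values per group")
    na, nb = a.size, b.size
    ssw = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    if ssw == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, ""
        return np.inf, 0.0, "degenerate: zero within-group variance"
    F, p = stats.f_oneway(a, b)
    return float(F), float(p), ""


# ---------------------------------------------------------------------------
# The model / results pair
# ---------------------------------------------------------------------------

class PhaseCompositeModel:
    """Composite analysis of annual anomalies conditioned on NAO-EA phase.

    Parameters
    ----------
    data
        Tidy frame with columns ``dataset, group, region, year, value``
        (one row per dataset-region-year), or a list of
        :class:`AnnualAnomalySeries` plus a ``groups`` mapping.
    assignment
        Winter phase assignment providing the composite of each year.

    Member-years are pooled across the datasets of a group ("inversions"
    vs "dgvms" mirror the two independent lines of evidence), which is
    the default reading of the pooled ANOVA; per-dataset means are also
    reported.
    """

    REQUIRED = ("dataset", "group", "region", "year", "value")

    def __init__(self, data: pd.DataFrame, assignment: PhaseAssignment):
        missing = set(self.REQUIRED) - set(data.columns)
        if missing:
            raise ValueError(f"data missing columns {sorted(missing)}")
        self.data = data.copy()
        self.assignment = assignment
        self.membership = composite_membership(assignment)

    @classmethod
    def from_series(cls, series: list[AnnualAnomalySeries], groups: dict[str, str],
                    assignment: PhaseAssignment) -> "PhaseCompositeModel":
        frames = []
        for s in series:
            f = s.to_frame()
            f["group"] = groups.get(s.dataset, "dgvms")
            frames.append(f)
        return cls(pd.concat(frames, ignore_index=True), assignment)

    def fit(self) -> "PhaseCompositeResults":
        rows, pair_rows, dataset_rows = [], [], []
        for (region, group), sub in self.data.groupby(["region", "group"]):
            pooled: dict[str, np.ndarray] = {}
            for comp, years in self.membership.items():
                vals = sub.loc[sub["year"].isin(years), "value"].to_numpy(dtype=float)
                pooled[comp] = vals[np.isfinite(vals)]
                if pooled[comp].size >= 2:
                    st = composite_significance(pooled[comp], comp, region, group)
                    rows.append(st.as_row())
                else:
                    rows.append({
                        "composite": comp, "region": region, "group": group,
                        "n": pooled[comp].size,
                        "mean": float(pooled[comp].mean()) if pooled[comp].size else np.nan,
                        "sd": np.nan, "F": np.nan, "p": np.nan, "flag": "n < 2",
                    })
            for ca, cb in combinations([c for c in COMPOSITES if c != "neutral"], 2):
                if pooled[ca].size >= 2 and pooled[cb].size >= 2:
                    F, p, flag = composite_pairwise_difference(pooled[ca], pooled[cb])
                    pair_rows.append({
                        "region": region, "group": group, "composite_a": ca,
                        "composite_b": cb, "F": F, "p": p, "flag": flag,
                    })
            for dataset, dsub in sub.groupby("dataset"):
                s = AnnualAnomalySeries(
                    dataset=dataset, region=region,
                    values=dsub.set_index("year")["value"].sort_index(),
                )
                for comp, (m, n) in composite_mean(s, self.membership).items():
                    dataset_rows.append({
                        "dataset": dataset, "group": group, "region": region,
                        "composite": comp, "mean": m, "n": n,
                    })
        return PhaseCompositeResults(
            model=self,
            stats=pd.DataFrame(rows),
            pairwise=pd.DataFrame(pair_rows),
            per_dataset=pd.DataFrame(dataset_rows),
        )


@dataclass
class PhaseCompositeResults:
    """Fitted composite means, their significance, and pairwise contrasts."""

    model: PhaseCompositeModel
    stats: pd.DataFrame
    pairwise: pd.DataFrame
    per_dataset: pd.DataFrame

    def composite_table(self, region: str, group: str) -> pd.DataFrame:
        sel = (self.stats["region"] == region) & (self.stats["group"] == group)
        return self.stats.loc[sel].set_index("composite")

    def ranked_composites(self, region: str, group: str) -> list[str]:
        """Composites ordered by decreasing pooled mean anomaly."""
        t = self.composite_table(region, group)
        return list(t["mean"].sort_values(ascending=False).index)

    def summary(self) -> str:
        lines = ["Phase-composite ANOVA summary",
                 "  one-sided: F = t^2 of composite mean vs 0, p ~ F(1, n-1)",
                 "  two-sided: two-group one-way ANOVA of composite pairs", ""]
        with pd.option_context("display.width", 120, "display.float_format",
                               lambda x: f"{x: .4f}"):
            lines.append(self.stats.to_string(index=False))
            if len(self.pairwise):
                lines.append("")
                lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Field-level and seasonal composites
# ---------------------------------------------------------------------------

def climate_composite_fields(anoms: AnomalyStack, membership: dict[str, list[int]],
                             window: str) -> dict[str, np.ndarray]:
    """Per-composite mean anomaly map over a seasonal window.

    For each composite, the 5-month window mean of every member year is
    averaged pixel-wise; empty composites give an all-NaN map.
    """
    years_avail = set(int(y) for y in np.unique(anoms.times.year))
    out = {}
    for comp, years in membership.items():
        fields = []
        for y in years:
            need = {y - 1, y} if window == "DecApr" else {y}
            if not need.issubset(years_avail):
                continue
            try:
                fields.append(seasonal_window_mean(anoms, window, y))
            except ValueError:
                continue
        if fields:
            out[comp] = np.mean(np.stack(fields), axis=0)
        else:
            out[comp] = np.full(anoms.grid.shape, np.nan)
    return out


@dataclass
class SeasonalCurveSet:
    """Monthly composite curves for NDVI, GPP and RECO with model spread.

    ``curves[composite]`` is a frame indexed by calendar month (1..12)
    with columns ``ndvi, gpp, reco, gpp_min, gpp_max, reco_min,
    reco_max``; the envelope is the min-max across ensemble members.
    """

    curves: dict[str, pd.DataFrame]
    region: str = ""

    def __post_init__(self):
        for comp, df in self.curves.items():
            if len(df) != 12:
                raise ValueError(f"{comp}: expected 12 monthly entries")
            for v in ("gpp", "reco"):
                bad = (df[f"{v}_min"] > df[v] + 1e-12) | (df[f"{v}_max"] < df[v] - 1e-12)
                if bad.any():
                    raise ValueError(f"{comp}: envelope does not bracket the {v} mean")


def _regional_monthly(anoms: AnomalyStack, mask: RegionMask) -> pd.Series:
    w = mask.weights
    series = (anoms.values * w).sum(axis=(1, 2))
    return pd.Series(series, index=anoms.times)


def _composite_month_means(series: pd.Series, years: list[int]) -> np.ndarray:
    sel = series[series.index.year.isin(years)]
    if sel.empty:
        return np.full(12, np.nan)
    return sel.groupby(sel.index.month).mean().reindex(range(1, 13)).to_numpy()


def seasonal_flux_curves(gpp_members: list[AnomalyStack], reco_members: list[AnomalyStack],
                         ndvi_monthly: pd.Series | None,
                         membership: dict[str, list[int]],
                         mask: RegionMask, region: str = "") -> SeasonalCurveSet:
    """Composite seasonal anomaly curves with the ensemble min-max envelope.

    ``gpp_members``/``reco_members`` are per-model anomaly stacks (PgC
    month^-1 cell^-1); ``ndvi_monthly`` is an optional regional monthly
    NDVI anomaly series sharing the time span.
    """
    if not gpp_members or not reco_members:
        raise ValueError("empty ensemble")
    gpp_reg = [_regional_monthly(a, mask) for a in gpp_members]
    reco_reg = [_regional_monthly(a, mask) for a in reco_members]
    curves = {}
    for comp, years in membership.items():
        g = np.stack([_composite_month_means(s, years) for s in gpp_reg])
        r = np.stack([_composite_month_means(s, years) for s in reco_reg])
        df = pd.DataFrame({
            "month": range(1, 13),
            "gpp": g.mean(axis=0), "gpp_min": g.min(axis=0), "gpp_max": g.max(axis=0),
            "reco": r.mean(axis=0), "reco_min": r.min(axis=0), "reco_max": r.max(axis=0),
        }).set_index("month")
        if ndvi_monthly is not None:
            df["ndvi"] = _composite_month_means(ndvi_monthly, years)
        else:
            df["ndvi"] = np.nan
        curves[comp] = df
    return SeasonalCurveSet(curves=curves, region=region)


def ensemble_envelope(series_set: list[AnnualAnomalySeries]) -> pd.DataFrame:
    """Per-year cross-dataset (mean, min, max), honoring each archive's span.

    The spread is the min-max across the datasets covering that year —
    the shaded-envelope convention, not +-sd.
    """
    if not series_set:
        raise ValueError("empty series set")
    frame = pd.DataFrame({s.dataset: s.values for s in series_set})
    return pd.DataFrame({
        "mean": frame.mean(axis=1, skipna=True),
        "min": frame.min(axis=1, skipna=True),
        "max": frame.max(axis=1, skipna=True),
        "n_datasets": frame.notna().sum(axis=1),
    })


def flux_moisture_dependence(gpp_regional: AnnualAnomalySeries,
                             sw_regional: AnnualAnomalySeries) -> tuple[float, float, float]:
    """OLS dependence of summer GPP anomalies on summer soil-water anomalies.

    Returns (slope, pearson_r, two_sided_p) over the common years.
    """
    common = gpp_regional.values.index.intersection(sw_regional.values.index)
    if len(common) < 5:
        raise ValueError("need at least 5 common years")
    x = sw_regional.values.loc[common].to_numpy(dtype=float)
    y = gpp_regional.values.loc[common].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("degenerate regressor: soil-water series has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)
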