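"""Seeded generator for every input the pipeline consumes.

The generator states a small world with known ground truth:

* two orthogonal dipole circulation patterns (NAO-like and EA-like)
  whose AR(1) monthly amplitudes drive a z500 stack plus white noise;
* a pseudo-ensemble of monthly GPP/RECO/NBP grids with a seasonal
  cycle, regional annual flux-anomaly effects conditioned on the joint
  winter phase of the two modes, and member noise (NBP = GPP - RECO
  identically);
* biweekly NDVI coupled to the GPP anomalies;
* phase-conditional climate anomaly stacks, with soil water optionally
  driving summer GPP for the moisture-dependence diagnostic.

Every artifact is reproducible bitwise from (config, seed); the
:class:`SyntheticTruth` ledger records the injected modes, phases and
effects for parameter-recovery tests.

Defaults state plausibly sized conditions for the European winter
analysis: 31 years (the 1982-2012 analog), an 11-member pseudo-DGVM
ensemble plus 3 pseudo-inversions, composite NBP effects of order
0.1 PgC yr^-1 against member noise of 0.1 PgC yr^-1, z500 dipoles of
tens of gpm against ~40 gpm monthly noise, and AR(1) amplitude
autocorrelation 0.3.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, STUDY_REGIONS, build_region_mask
from .registry import require_variable
from .series import TeleconnectionSeries
from .stacks import BiweeklyFieldStack, MonthlyFieldStack, month_index
from .teleconnections import classify_phases, winter_index

START_YEAR = 1982  # calendar labels of the synthetic record


@dataclass(frozen=True)
class DipoleSpec:
    """A two-lobe pattern: Gaussian bumps of opposite sign.

    ``amplitude`` is the peak height (gpm for z500 modes); the northern
    lobe is the *negative* one so that a positive amplitude gives the
    positive-phase sign convention (low heights at the northern center).
    """

    north_lat: float
    north_lon: float
    south_lat: float
    south_lon: float
    width_deg: float = 12.0
    amplitude: float = 1.0

    def evaluate(self, grid: GridSpec) -> np.ndarray:
        lat = grid.lat[:, None]
        lon = grid.lon[None, :]
        if not (grid.lat.min() <= self.north_lat <= grid.lat.max()
                and grid.lat.min() <= self.south_lat <= grid.lat.max()
                and grid.lon.min() <= self.north_lon <= grid.lon.max()
                and grid.lon.min() <= self.south_lon <= grid.lon.max()):
            raise ValueError("dipole centers outside the grid domain")

        def lobe(clat, clon):
            # compress longitude distance by cos(lat) for roundish lobes
            dx = (lon - clon) * np.cos(np.deg2rad(clat))
            dy = lat - clat
            return np.exp(-(dx**2 + dy**2) / (2.0 * self.width_deg**2))

        return self.amplitude * (lobe(self.south_lat, self.south_lon)
                                 - lobe(self.north_lat, self.north_lon))


# effect sizes beta[composite] in PgC yr^-1 for the continental region,
# signs following the qualitative flux findings (in-phase negative pair
# enhanced via GPP; anti-phase reduced via GPP drop or RECO rise)
DEFAULT_BETA = {
    "NAO-EA-": 0.10,
    "NAO+EA-": -0.05,
    "NAO-EA+": -0.05,
    "NAO+EA+": 0.02,
    "neutral": 0.0,
}

# fraction of each composite's NBP effect routed through GPP (the
# remainder enters as an opposite-signed RECO effect)
DEFAULT_GPP_SPLIT = {
    "NAO-EA-": 1.0,
    "NAO+EA-": 1.0,
    "NAO-EA+": 0.0,
    "NAO+EA+": 0.5,
    "neutral": 1.0,
}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic world; defaults are the stated world."""

    n_years: int = 31
    seed: int = 0
    # flux grid: 2 deg over the European window
    flux_grid: tuple = (30.0, 75.0, -15.0, 60.0, 2.0)
    # z500 grid: 2 deg over the North-Atlantic analysis sector
    z500_grid: tuple = (20.0, 80.0, -90.0, 50.0, 2.0)
    nao_dipole: DipoleSpec = field(default_factory=lambda: DipoleSpec(
        north_lat=64.0, north_lon=-25.0, south_lat=38.0, south_lon=-25.0,
        width_deg=8.0, amplitude=80.0))
    ea_dipole: DipoleSpec = field(default_factory=lambda: DipoleSpec(
        north_lat=52.0, north_lon=-28.0, south_lat=28.0, south_lon=-8.0,
        width_deg=8.0, amplitude=60.0))
    ar1_rho: float = 0.3
    z500_noise_sd: float = 40.0  # gpm, per month per cell
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    gpp_split: dict = field(default_factory=lambda: dict(DEFAULT_GPP_SPLIT))
    effect_region: str = "europe"
    seasonal_gpp_amplitude: float = 1.2  # PgC month^-1, continental peak
    flux_noise_sd: float = 0.10  # PgC yr^-1, continental annual, per member
    cell_noise_sd: float = 1e-4  # PgC month^-1 cell^-1, white texture
    effect_months: tuple = (5, 6, 7, 8, 9)  # raised-cosine injection window
    n_members: int = 11
    n_inversions: int = 3
    ndvi_gain: float = 5.0  # NDVI units per (PgC month^-1 cell^-1) regional scale
    ndvi_noise_sd: float = 0.01
    ndvi_baseline: float = 0.35
    ndvi_seasonal_amplitude: float = 0.25
    climate_pattern_amplitude: float = 1.0  # multiplies per-variable templates
    climate_noise_sd: float = 0.5  # native units, per month per cell
    gpp_sw_slope: float = 0.0  # PgC yr^-1 per (% volume) regional SW anomaly
    sw_annual_sd: float = 1.0  # % volume, regional summer SW anomaly scale

    def __post_init__(self):
        if self.n_years < 12:
            raise ValueError("n_years must be at least 12")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("AR(1) rho must lie in (-1, 1)")
        for name in ("z500_noise_sd", "flux_noise_sd", "cell_noise_sd",
                     "ndvi_noise_sd", "climate_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ndvi_gain < 0:
            raise ValueError("ndvi_gain must be >= 0")

    def make_flux_grid(self) -> GridSpec:
        lat0, lat1, lon0, lon1, d = self.flux_grid
        return GridSpec.regular(lat0, lat1, lon0, lon1, d)

    def make_z500_grid(self) -> GridSpec:
        lat0, lat1, lon0, lon1, d = self.z500_grid
        return GridSpec.regular(lat0, lat1, lon0, lon1, d)

    @property
    def years(self) -> np.ndarray:
        return np.arange(START_YEAR, START_YEAR + self.n_years)


@dataclass
class SyntheticTruth:
    """Ledger of everything injected: sufficient to recompute any artifact."""

    config: SyntheticConfig
    amplitudes: pd.DataFrame  # monthly NAO/EA amplitude series
    winter_phases: pd.DataFrame  # winter_year -> nao, ea, composite
    patterns: dict  # name -> spatial pattern on z500 grid (orthogonalized)
    standardized_patterns: dict  # name -> expected pattern of a standardized analysis
    injected_annual: pd.DataFrame | None = None  # year -> injected NBP/GPP/RECO (PgC yr^-1)
    sw_annual: pd.Series | None = None  # year -> regional summer SW anomaly

    def composite_years(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for y, row in self.winter_phases.iterrows():
            out.setdefault(row["composite"], []).append(int(y))
        return out


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Standardized AR(1): unit marginal variance for any |rho| < 1."""
    innov_sd = np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


# ---------------------------------------------------------------------------
# Indices and z500
# ---------------------------------------------------------------------------

def simulate_mode_indices(config: SyntheticConfig) -> tuple[
        TeleconnectionSeries, TeleconnectionSeries, SyntheticTruth]:
    """Two independent AR(1) standardized monthly index series plus truth.

    The record spans Dec of the year before the first labelled winter
    through Dec of the last year, so every winter has a full DJF.
    """
    n_months = config.n_years * 12 + 1  # lead with Dec(START_YEAR - 1)
    times = month_index(f"{START_YEAR - 1}-12", n_months)
    rng_nao = _spawn(config.seed, 1)
    rng_ea = _spawn(config.seed, 2)
    nao = pd.Series(_ar1(rng_nao, n_months, config.ar1_rho), index=times)
    ea = pd.Series(_ar1(rng_ea, n_months, config.ar1_rho), index=times)
    nao_s = TeleconnectionSeries(name="NAO", values=nao)
    ea_s = TeleconnectionSeries(name="EA", values=ea)
    assignment = classify_phases(winter_index(nao_s), winter_index(ea_s))
    phases = assignment.table[["nao", "ea", "composite"]].copy()
    amp = pd.DataFrame({"NAO": nao, "EA": ea})
    grid = config.make_z500_grid()
    p_nao, p_ea = _orthogonal_patterns(config, grid)
    truth = SyntheticTruth(
        config=config, amplitudes=amp, winter_phases=phases,
        patterns={"NAO": p_nao, "EA": p_ea},
        standardized_patterns=_standardized_patterns(config, grid, p_nao, p_ea),
    )
    return nao_s, ea_s, truth


def _orthogonal_patterns(config: SyntheticConfig, grid: GridSpec):
    """Dipole patterns, Gram-Schmidt orthogonalized under area weights."""
    w = np.cos(np.deg2rad(grid.lat))[:, None] * np.ones((1, grid.lon.size))
    p1 = config.nao_dipole.evaluate(grid)
    p2 = config.ea_dipole.evaluate(grid)
    proj = np.sum(w * p1 * p2) / np.sum(w * p1 * p1)
    p2 = p2 - proj * p1
    return p1, p2


def _standardized_patterns(config: SyntheticConfig, grid: GridSpec,
                           p_nao: np.ndarray, p_ea: np.ndarray) -> dict:
    """Expected loading shapes of a per-pixel standardized analysis.

    Pixel-wise standardization divides the field by its local monthly
    sd, sqrt(P_nao^2 + P_ea^2 + noise^2) for unit-variance amplitudes;
    the patterns a standardized PCA can recover are the raw dipoles
    scaled by that factor.
    """
    sd = np.sqrt(p_nao**2 + p_ea**2 + config.z500_noise_sd**2)
    return {"NAO": p_nao / sd, "EA": p_ea / sd}


def simulate_z500_stack(config: SyntheticConfig, nao: TeleconnectionSeries,
                        ea: TeleconnectionSeries) -> MonthlyFieldStack:
    """z500 = A_NAO * P_NAO + A_EA * P_EA + iid noise, on the z500 grid."""
    grid = config.make_z500_grid()
    p_nao, p_ea = _orthogonal_patterns(config, grid)
    times = nao.values.index
    if not times.equals(ea.values.index):
        raise ValueError("index series must share their time axis")
    a = nao.values.to_numpy()[:, None, None]
    b = ea.values.to_numpy()[:, None, None]
    rng = _spawn(config.seed, 3)
    noise = rng.standard_normal((len(times),) + grid.shape) * config.z500_noise_sd
    values = a * p_nao[None] + b * p_ea[None] + noise
    return MonthlyFieldStack(variable="Z500", units="gpm", times=times,
                             values=values, grid=grid)


# ---------------------------------------------------------------------------
# Fluxes
# ---------------------------------------------------------------------------

def _raised_cosine_weights(months: tuple[int, ...]) -> np.ndarray:
    """Smooth monthly weights over a window, summing to 1 (12-vector)."""
    w = np.zeros(12)
    n = len(months)
    for i, m in enumerate(months):
        w[m - 1] = 1.0 - np.cos(2.0 * np.pi * (i + 0.5) / n)
    return w / w.sum()


def _seasonal_cycle(config: SyntheticConfig, month: np.ndarray) -> np.ndarray:
    """Continental GPP seasonal cycle, peaking mid-summer (PgC month^-1)."""
    phase = 2.0 * np.pi * (month - 1) / 12.0
    return config.seasonal_gpp_amplitude * 0.5 * (1.0 - np.cos(phase - np.pi / 6.0))


def simulate_flux_ensemble(config: SyntheticConfig, truth: SyntheticTruth,
                           n_members: int | None = None, member_offset: int = 0,
                           ) -> list[dict[str, MonthlyFieldStack]]:
    """Monthly GPP/RECO/NBP stacks for a pseudo-model ensemble.

    Each member's flux is a shared seasonal cycle plus the composite
    effect of its year (beta distributed over the effect-window months
    and the effect-region cells), plus member noise at the continental
    annual scale and per-cell white texture. NBP = GPP - RECO holds
    identically; the expected injected continental annual NBP anomaly
    of a year equals beta[composite of its winter].

    When the truth carries a soil-water series and a nonzero coupling
    slope, slope * SW(year) enters GPP alongside beta.
    """
    n_members = config.n_members if n_members is None else n_members
    grid = config.make_flux_grid()
    box = STUDY_REGIONS[config.effect_region]
    mask = build_region_mask(box, grid)
    # normalized so that the mask-weighted regional integral of the
    # distributed effect equals the injected total exactly (fractional
    # boundary cells would otherwise be double-discounted)
    w_cells = mask.weights / np.sum(mask.weights**2)
    nt = config.n_years * 12
    times = month_index(f"{START_YEAR}-01", nt)
    month = times.month.to_numpy()
    year = times.year.to_numpy()
    w_month = _raised_cosine_weights(config.effect_months)

    comp_of_year = truth.winter_phases["composite"].to_dict()
    beta_nbp = np.array([config.beta.get(comp_of_year.get(int(y), "neutral"), 0.0)
                         for y in config.years])
    split = np.array([config.gpp_split.get(comp_of_year.get(int(y), "neutral"), 1.0)
                      for y in config.years])
    sw_term = np.zeros(config.n_years)
    if truth.sw_annual is not None and config.gpp_sw_slope != 0.0:
        sw_term = config.gpp_sw_slope * truth.sw_annual.reindex(config.years).fillna(0.0).to_numpy()

    beta_gpp = beta_nbp * split + sw_term
    beta_reco = -(beta_nbp * (1.0 - split))  # positive = more respiration

    cycle = _seasonal_cycle(config, month)  # continental PgC month^-1
    base_gpp = cycle[:, None, None] * w_cells[None]  # per-cell PgC month^-1
    base_reco = 0.6 * base_gpp  # fixed autotrophic+heterotrophic share

    truth.injected_annual = pd.DataFrame(
        {
            "nbp": beta_gpp - beta_reco,
            "gpp": beta_gpp,
            "reco": beta_reco,
            "composite": [comp_of_year.get(int(y), "neutral") for y in config.years],
        },
        index=config.years,
    )
    members = []
    for im in range(n_members):
        rng = _spawn(config.seed, 100 + member_offset + im)
        # continental annual member noise, split over GPP months
        noise_gpp_y = rng.standard_normal(config.n_years) * config.flux_noise_sd * 0.7
        noise_reco_y = rng.standard_normal(config.n_years) * config.flux_noise_sd * 0.7
        gpp_y = beta_gpp + noise_gpp_y
        reco_y = beta_reco + noise_reco_y
        yi = year - START_YEAR
        inject_gpp = gpp_y[yi] * w_month[month - 1]
        inject_reco = reco_y[yi] * w_month[month - 1]
        gpp = base_gpp + inject_gpp[:, None, None] * w_cells[None]
        reco = base_reco + inject_reco[:, None, None] * w_cells[None]
        if config.cell_noise_sd > 0:
            gpp = gpp + rng.standard_normal(gpp.shape) * config.cell_noise_sd
            reco = reco + rng.standard_normal(reco.shape) * config.cell_noise_sd
        nbp = gpp - reco
        stacks = {
            v: MonthlyFieldStack(variable=v, units="PgC month-1 cell-1",
                                 times=times, values=arr, grid=grid)
            for v, arr in (("GPP", gpp), ("RECO", reco), ("NBP", nbp))
        }
        members.append(stacks)
    return members


# ---------------------------------------------------------------------------
# NDVI
# ---------------------------------------------------------------------------

def simulate_ndvi_stack(config: SyntheticConfig,
                        gpp: MonthlyFieldStack) -> BiweeklyFieldStack:
    """Biweekly NDVI: baseline cycle + gain * GPP anomaly + noise, clipped.

    Each month of the GPP record maps onto two biweekly samples; the
    GPP *anomaly* is taken against the per-calendar-month mean of the
    supplied stack, so a zero-gain simulation integrates to zero annual
    NDVI anomaly by construction.
    """
    years = np.unique(gpp.times.year)
    n_years = years.size
    month = gpp.times.month.to_numpy()
    clim = np.zeros((12,) + gpp.grid.shape)
    for m in range(1, 13):
        clim[m - 1] = gpp.values[month == m].mean(axis=0)
    anom = gpp.values - clim[month - 1]
    biweekly = np.repeat(anom.reshape(n_years, 12, *gpp.grid.shape), 2, axis=1)
    s = np.arange(24)
    cycle = config.ndvi_baseline + config.ndvi_seasonal_amplitude * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * (s + 1) / 24.0 - np.pi / 6.0))
    rng = _spawn(config.seed, 7)
    values = cycle[None, :, None, None] + config.ndvi_gain * biweekly
    if config.ndvi_noise_sd > 0:
        values = values + rng.standard_normal(values.shape) * config.ndvi_noise_sd
    values = np.clip(values, -1.0, 1.0)
    return BiweeklyFieldStack(years=years, values=values, grid=gpp.grid)


# ---------------------------------------------------------------------------
# Climate stacks
# ---------------------------------------------------------------------------

# per-variable template amplitudes (native units) for a unit pattern
CLIMATE_TEMPLATE_SCALE = {
    "SLP": 4.0, "Z500": 40.0, "T2M": 2.0, "SW": 2.0, "SD": 5.0,
    "CLOUD": 8.0, "HT": 10.0, "VT": 5.0, "PDSI": 1.0,
}

# which 5-month window a variable's composite pattern occupies
CLIMATE_WINDOW_MONTHS = {
    "SLP": (12, 1, 2, 3, 4), "Z500": (12, 1, 2, 3, 4), "SD": (12, 1, 2, 3, 4),
    "CLOUD": (12, 1, 2, 3, 4), "HT": (12, 1, 2, 3, 4), "VT": (12, 1, 2, 3, 4),
    "T2M": (5, 6, 7, 8, 9), "SW": (5, 6, 7, 8, 9), "PDSI": (5, 6, 7, 8, 9),
}

# composite -> sign of the injected pattern (anti-phase combinations get
# weaker-amplitude patterns, mirroring their meandering circulation)
COMPOSITE_PATTERN_SIGN = {
    "NAO-EA-": -1.0, "NAO+EA+": 1.0, "NAO+EA-": 0.5, "NAO-EA+": -0.5,
    "neutral": 0.0,
}


def climate_pattern(config: SyntheticConfig, variable: str,
                    grid: GridSpec) -> np.ndarray:
    """The unit spatial template of a climate variable's composite anomaly."""
    scale = CLIMATE_TEMPLATE_SCALE[variable]
    bump = DipoleSpec(north_lat=62.0, north_lon=15.0, south_lat=42.0,
                      south_lon=10.0, width_deg=10.0,
                      amplitude=scale * config.climate_pattern_amplitude)
    return bump.evaluate(grid)


def simulate_climate_stack(config: SyntheticConfig, truth: SyntheticTruth,
                           variable: str) -> MonthlyFieldStack:
    """Phase-conditional climate anomaly stack on the flux grid.

    The composite of each winter scales a fixed spatial template over
    the variable's window months; white noise is added everywhere. For
    SW, the per-year regional summer anomaly is drawn first, recorded
    in the truth ledger (driving GPP when the coupling slope is
    nonzero), and injected uniformly over the effect region.
    """
    info = require_variable(variable)
    if variable not in CLIMATE_TEMPLATE_SCALE:
        raise ValueError(f"no climate template registered for {variable!r}")
    grid = config.make_flux_grid()
    nt = config.n_years * 12
    times = month_index(f"{START_YEAR}-01", nt)
    month = times.month.to_numpy()
    year = times.year.to_numpy()
    window = CLIMATE_WINDOW_MONTHS[variable]
    pattern = climate_pattern(config, variable, grid)
    comp_of_year = truth.winter_phases["composite"].to_dict()

    # window month -> attributed year (Dec belongs to the next winter)
    attributed = year + (month == 12).astype(int)
    sign = np.array([
        COMPOSITE_PATTERN_SIGN.get(comp_of_year.get(int(y), "neutral"), 0.0)
        for y in attributed
    ])
    in_window = np.isin(month, window)
    amp = np.where(in_window, sign, 0.0)
    values = amp[:, None, None] * pattern[None]

    rng = _spawn(config.seed, 11 + sum(ord(c) for c in variable) % 50)
    if variable == "SW":
        rng_sw = _spawn(config.seed, 8)
        sw_annual = pd.Series(
            rng_sw.standard_normal(config.n_years) * config.sw_annual_sd,
            index=config.years,
        )
        truth.sw_annual = sw_annual
        box = STUDY_REGIONS[config.effect_region]
        mask = build_region_mask(box, grid)
        summer = np.isin(month, (5, 6, 7, 8, 9))
        yi = year - START_YEAR
        add = np.where(summer, sw_annual.to_numpy()[yi], 0.0)
        values = values + add[:, None, None] * (mask.weights > 0)[None]
    if config.climate_noise_sd > 0:
        values = values + rng.standard_normal(values.shape) * config.climate_noise_sd
    return MonthlyFieldStack(variable=variable, units=info.default_units,
                             times=times, values=values, grid=grid)


# ---------------------------------------------------------------------------
# Whole-world convenience and the CPC-dialect stand-in tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, from one seed."""

    config: SyntheticConfig
    truth: SyntheticTruth
    nao: TeleconnectionSeries
    ea: TeleconnectionSeries
    z500: MonthlyFieldStack
    members: list[dict[str, MonthlyFieldStack]]  # pseudo-DGVMs
    inversions: list[dict[str, MonthlyFieldStack]]
    ndvi: BiweeklyFieldStack
    climate: dict[str, MonthlyFieldStack]


def simulate_world(config: SyntheticConfig | None = None,
                   climate_variables=("T2M", "SW", "SD", "SLP", "CLOUD"),
                   with_z500: bool = True) -> SyntheticWorld:
    """Generate the full synthetic input set in dependency order."""
    config = config or SyntheticConfig()
    nao, ea, truth = simulate_mode_indices(config)
    z500 = simulate_z500_stack(config, nao, ea) if with_z500 else None
    climate = {}
    order = sorted(climate_variables, key=lambda v: v != "SW")  # SW first
    for v in order:
        climate[v] = simulate_climate_stack(config, truth, v)
    members = simulate_flux_ensemble(config, truth)
    inversions = simulate_flux_ensemble(config, truth,
                                        n_members=config.n_inversions,
                                        member_offset=500)
    ndvi = simulate_ndvi_stack(config, members[0]["GPP"])
    return SyntheticWorld(config=config, truth=truth, nao=nao, ea=ea,
                          z500=z500, members=members, inversions=inversions,
                          ndvi=ndvi, climate=climate)


# Winter labelling of the SYNTHETIC stand-in index tables. This is a
# synthetic reconstruction of the published phase structure of winters
# 1982-2012 (four in-phase-positive winters, the 1985/1996/1997 strong
# negative-pair winters, anti-phase 1982-1984 and the six-year
# anti-phase run 1998-2003); it is NOT the real observational record.
_STANDIN_LABELS = {
    1982: ("+", "-"), 1983: ("-", "+"), 1984: ("-", "+"),
    1985: ("-", "-"), 1986: ("+", "+"), 1987: ("-", "0"),
    1988: ("0", "0"), 1989: ("+", "+"), 1990: ("+", "0"),
    1991: ("0", "-"), 1992: ("+", "+"), 1993: ("0", "0"),
    1994: ("0", "0"), 1995: ("+", "+"), 1996: ("-", "-"),
    1997: ("-", "-"), 1998: ("+", "-"), 1999: ("-", "+"),
    2000: ("+", "-"), 2001: ("-", "+"), 2002: ("+", "-"),
    2003: ("-", "+"), 2004: ("0", "0"), 2005: ("-", "0"),
    2006: ("0", "-"), 2007: ("+", "0"), 2008: ("0", "+"),
    2009: ("0", "0"), 2010: ("0", "-"), 2011: ("0", "0"),
    2012: ("0", "0"),
}

_PHASE_LEVEL = {"-": -1.1, "0": 0.0, "+": 1.1}


def standin_index_tables(out_dir) -> tuple[Path, Path]:
    """Write the SYNTHETIC stand-in NAO/EA monthly tables (CPC dialect).

    Deterministic by construction: winter DJF months take the phase
    band level plus a small within-band offset; non-winter months carry
    filler values, with a few -99.9 sentinels to exercise masking.
    Returns the two file paths (synthetic_cpc_nao.txt, synthetic_cpc_ea.txt).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, name in ((0, "nao"), (1, "ea")):
        lines = []
        for ym in month_index("1981-12", 31 * 12 + 1):
            y, m = ym.year, ym.month
            winter = y + 1 if m == 12 else y
            if m in (12, 1, 2) and winter in _STANDIN_LABELS:
                level = _PHASE_LEVEL[_STANDIN_LABELS[winter][k]]
                jitter = 0.15 * np.cos(2.0 * np.pi * ((winter * 3 + m + k) % 7) / 7.0)
                value = level + jitter
            elif (y + m + k) % 29 == 0:
                value = -99.9  # sentinel in a non-winter month
            else:
                value = round(np.sin(0.7 * y + m + k) * 0.8, 2)
            lines.append(f"{y:5d} {m:3d} {value:8.2f}")
        p = out_dir / f"synthetic_cpc_{name}.txt"
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    return tuple(paths)


def save_truth(truth: SyntheticTruth, path) -> None:
    """Serialize the truth ledger to JSON (arrays as lists)."""
    cfg = asdict(truth.config)
    cfg["nao_dipole"] = asdict(truth.config.nao_dipole)
    cfg["ea_dipole"] = asdict(truth.config.ea_dipole)
    payload = {
        "config": cfg,
        "winter_phases": truth.winter_phases.reset_index()
            .rename(columns={"index": "winter_year"}).to_dict(orient="list"),
        "amplitudes": {
            "time": [str(p) for p in truth.amplitudes.index],
            "NAO": truth.amplitudes["NAO"].tolist(),
            "EA": truth.amplitudes["EA"].tolist(),
        },
    }
    if truth.injected_annual is not None:
        payload["injected_annual"] = truth.injected_annual.reset_index()\
            .rename(columns={"index": "year"}).to_dict(orient="list")
    Path(path).write_text(json.dumps(payload, indent=1, default=float))
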