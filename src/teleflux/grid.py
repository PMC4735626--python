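"""Regular lat/lon grids, region boxes and fractional-overlap masks.

Conventions (fixed package-wide):

* cell registration is *centers*; bounds are reconstructed as midpoints
  between neighbouring centers (edge cells get symmetric half-widths);
* longitude canon is degrees east in [-180, 180), latitude ascending;
* spatial weights use the cos-latitude approximation for cell area,
  adequate at the 0.5-4 degree resolutions handled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6.371e6

_UNIFORM_TOL = 1e-6  # degrees


def _check_axis(x: np.ndarray, name: str) -> None:
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} axis must be a non-empty 1-d array")
    if x.size > 1:
        d = np.diff(x)
        if not np.all(d > 0):
            raise ValueError(f"{name} axis must be strictly ascending")
        if np.ptp(d) > _UNIFORM_TOL:
            raise ValueError(f"{name} axis spacing not uniform within {_UNIFORM_TOL} deg")


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid defined by its cell-center coordinates."""

    lat: np.ndarray  # degrees north, ascending
    lon: np.ndarray  # degrees east in [-180, 180), ascending
    resolution: tuple | None = None  # (dlat, dlon) hint for 1-cell axes

    def __post_init__(self):
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)
        _check_axis(lat, "lat")
        _check_axis(lon, "lon")
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitudes must lie in [-90, 90]")
        if np.any(lon < -180) or np.any(lon >= 180):
            raise ValueError("longitudes must lie in [-180, 180)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def dlat(self) -> float:
        return float(np.diff(self.lat).mean()) if self.lat.size > 1 else np.nan

    @property
    def dlon(self) -> float:
        return float(np.diff(self.lon).mean()) if self.lon.size > 1 else np.nan

    def _bounds(self, centers: np.ndarray, fallback: float) -> np.ndarray:
        """Cell edges as midpoints between centers; (n+1,) array."""
        if centers.size == 1:
            h = fallback / 2.0
            return np.array([centers[0] - h, centers[0] + h])
        mids = (centers[:-1] + centers[1:]) / 2.0
        first = centers[0] - (mids[0] - centers[0])
        last = centers[-1] + (centers[-1] - mids[-1])
        return np.concatenate([[first], mids, [last]])

    def lat_bounds(self, default_width: float = 1.0) -> np.ndarray:
        w = self.resolution[0] if self.resolution else default_width
        b = self._bounds(self.lat, w)
        return np.clip(b, -90.0, 90.0)

    def lon_bounds(self, default_width: float = 1.0) -> np.ndarray:
        w = self.resolution[1] if self.resolution else default_width
        return self._bounds(self.lon, w)

    @classmethod
    def regular(cls, lat0: float, lat1: float, lon0: float, lon1: float,
                dlat: float, dlon: float | None = None) -> "GridSpec":
        """Grid of cells whose *edges* tile [lat0,lat1] x [lon0,lon1]."""
        dlon = dlat if dlon is None else dlon
        lat = np.arange(lat0 + dlat / 2.0, lat1, dlat)
        lon = np.arange(lon0 + dlon / 2.0, lon1, dlon)
        return cls(lat=lat, lon=lon, resolution=(dlat, dlon))

    def __eq__(self, other):
        return (isinstance(other, GridSpec)
                and self.lat.shape == other.lat.shape
                and self.lon.shape == other.lon.shape
                and np.allclose(self.lat, other.lat, atol=1e-9)
                and np.allclose(self.lon, other.lon, atol=1e-9))


def area_weights(grid: GridSpec) -> np.ndarray:
    """(nlat, nlon) weights proportional to cos(lat_center), summing to 1."""
    w = np.cos(np.deg2rad(grid.lat))[:, None] * np.ones((1, grid.lon.size))
    return w / w.sum()


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Spherical cell areas in m^2, R^2 * (sin lat_hi - sin lat_lo) * dlon.

    On a uniform grid this equals the cos(lat_center) approximation up
    to a constant factor, while keeping conservative regridding exactly
    conservative.
    """
    latb = np.deg2rad(grid.lat_bounds())
    lonb = np.deg2rad(grid.lon_bounds())
    dsin = np.diff(np.sin(latb))
    dlam = np.diff(lonb)
    return EARTH_RADIUS_M**2 * dsin[:, None] * dlam[None, :]


@dataclass(frozen=True)
class RegionBox:
    """A lat/lon rectangle, optionally with nested exclusion boxes."""

    name: str
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    exclusions: tuple["RegionBox", ...] = field(default=())

    def __post_init__(self):
        if not self.lon_min < self.lon_max:
            raise ValueError(f"{self.name}: lon_min must be < lon_max")
        if not self.lat_min < self.lat_max:
            raise ValueError(f"{self.name}: lat_min must be < lat_max")
        object.__setattr__(self, "exclusions", tuple(self.exclusions))
        for ex in self.exclusions:
            inside = (ex.lon_min >= self.lon_min and ex.lon_max <= self.lon_max
                      and ex.lat_min >= self.lat_min and ex.lat_max <= self.lat_max)
            if not inside:
                raise ValueError(f"exclusion {ex.name} not inside {self.name}")

    def contains(self, lat: float, lon: float) -> bool:
        if not (self.lat_min <= lat <= self.lat_max
                and self.lon_min <= lon <= self.lon_max):
            return False
        return not any(
            ex.lat_min <= lat <= ex.lat_max and ex.lon_min <= lon <= ex.lon_max
            for ex in self.exclusions
        )


# The four analysis regions of the European-continent study, as printed
# box definitions (Great Britain removed from central Europe by a box).
GREAT_BRITAIN_BOX = RegionBox("great_britain", -5.0, 2.0, 49.9, 53.0)

STUDY_REGIONS: dict[str, RegionBox] = {
    "iberia": RegionBox("iberia", -11.0, 3.5, 34.0, 44.0),
    "central_europe": RegionBox("central_europe", -5.0, 25.0, 44.0, 53.0,
                                exclusions=(GREAT_BRITAIN_BOX,)),
    "western_russia": RegionBox("western_russia", 29.0, 60.0, 46.0, 62.0),
    "scandinavia": RegionBox("scandinavia", 4.5, 29.0, 56.0, 71.0),
    "europe": RegionBox("europe", -15.0, 60.0, 30.0, 75.0),
}

# z500 analysis window for the circulation-mode PCA (North Atlantic sector).
NORTH_ATLANTIC_DOMAIN = RegionBox("north_atlantic", -90.0, 50.0, 20.0, 80.0)


@dataclass(frozen=True)
class RegionMask:
    """Fractional cell membership of a region on a specific grid."""

    grid: GridSpec
    weights: np.ndarray  # (nlat, nlon) in [0, 1]
    name: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.shape:
            raise ValueError("mask weights do not match grid shape")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("mask weights must lie in [0, 1]")
        object.__setattr__(self, "weights", np.clip(w, 0.0, 1.0))


def _overlap_fraction(b0: np.ndarray, b1: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fraction of each interval [b0, b1] covered by [lo, hi]."""
    width = b1 - b0
    cover = np.clip(np.minimum(b1, hi) - np.maximum(b0, lo), 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(width > 0, cover / width, 0.0)


def _box_fraction(box: RegionBox, grid: GridSpec) -> np.ndarray:
    latb = grid.lat_bounds()
    lonb = grid.lon_bounds()
    fl = _overlap_fraction(latb[:-1], latb[1:], box.lat_min, box.lat_max)
    fn = _overlap_fraction(lonb[:-1], lonb[1:], box.lon_min, box.lon_max)
    return fl[:, None] * fn[None, :]


def build_region_mask(box: RegionBox, grid: GridSpec) -> RegionMask:
    """Fractional-overlap weights of ``box`` on ``grid``; exclusions zeroed.

    The weight of a cell is the fraction of its (rectangular, center-
    registered) footprint inside the box, minus the fraction inside any
    exclusion box, clipped to [0, 1].
    """
    w = _box_fraction(box, grid)
    for ex in box.exclusions:
        w = w - _box_fraction(ex, grid)
    w = np.clip(w, 0.0, 1.0)
    if not np.any(w > 0):
        raise ValueError(f"empty mask: region {box.name!r} does not overlap the grid")
    return RegionMask(grid=grid, weights=w, name=box.name)
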