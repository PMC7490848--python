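"""The patch grid: environmental fields, area masks, distance indices, and
the synthetic forcing generator.

The seascape is a two-dimensional grid of square cells (default 60 km edge on
a local equal-distance approximation).  Row 0 is the southern edge; ``y``
increases northward and ``x`` eastward.  Depth is negative below sea level.
Area masks follow the stock's geography: a shelf-edge corridor
(-550 m < depth < -50 m) along which spawning and feeding migrations run, a
shallow nursery area (depth >= -200 m), an overwintering area, and a dynamic
spawning area (shelf-edge cells at 10-14 degC).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .dates import (
    DAYS_PER_YEAR,
    MONTH_STARTS,
    month_of_doy,
)

__all__ = [
    "Seascape",
    "Forcing",
    "build_grid",
    "synthetic_bathymetry",
    "distance_field",
    "spawning_mask",
    "generate_synthetic_forcing",
    "update_forcing",
    "daylength_fraction",
    "read_raster_csv",
    "write_raster_csv",
    "LAND",
    "UNREACHABLE",
]

KM_PER_DEG_LAT = 111.2

# sentinels for distance fields
LAND = -1
UNREACHABLE = -2

# BFS adjacency: 4-neighbour (von Neumann), matching the foraging model's
# four sensed neighbours
NEIGHBOURS_4 = ((0, 1), (0, -1), (1, 0), (-1, 0))


class SeascapeError(ValueError):
    pass


@dataclass
class Seascape:
    """Gridded fields and masks.  All 2-D arrays are shaped (ny, nx)."""

    depth: np.ndarray            # m, negative below sea level
    lat: np.ndarray              # decimal degrees, per cell centre
    lon: np.ndarray
    cell_km: float = 60.0

    # environmental fields (filled by update_forcing)
    X: np.ndarray = None         # phytoplankton biomass, g m-2
    SST: np.ndarray = None       # degC
    p_photo: np.ndarray = None   # proportion of 24 h
    U: np.ndarray = None         # zonal current, km h-1
    V: np.ndarray = None         # meridional current, km h-1
    D: np.ndarray = None         # local mackerel density, g patch-1

    # masks
    ocean: np.ndarray = None
    shelf_edge: np.ndarray = None
    narea: np.ndarray = None
    owarea: np.ndarray = None
    sarea: np.ndarray = None

    # destinations and distance indices
    spawn_dest: tuple[int, int] = None   # (y, x)
    feed_dest: tuple[int, int] = None
    spawn_dist: np.ndarray = None
    feed_dist: np.ndarray = None

    spawn_sector_max_lat: float = None   # spawning restricted south of this

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.ny, self.nx = self.depth.shape
        if self.ocean is None:
            self.ocean = self.depth < 0.0
        if not self.ocean.any():
            raise SeascapeError("bathymetry contains no ocean patches")
        self.shelf_edge = self.ocean & (self.depth > -550.0) & (self.depth < -50.0)
        zeros = lambda: np.zeros((self.ny, self.nx))
        for name in ("X", "SST", "p_photo", "U", "V", "D"):
            if getattr(self, name) is None:
                setattr(self, name, zeros())
        for name in ("narea", "owarea", "sarea"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((self.ny, self.nx), dtype=bool))

    # -- geometry helpers ------------------------------------------------
    def in_bounds(self, y: int, x: int) -> bool:
        return 0 <= y < self.ny and 0 <= x < self.nx

    def is_ocean(self, y: int, x: int) -> bool:
        return self.in_bounds(y, x) and bool(self.ocean[y, x])

    def patches_within(self, y: int, x: int, radius: float) -> list[tuple[int, int]]:
        """Ocean patches within Euclidean ``radius`` (in patch units)."""
        r = int(np.floor(radius))
        out = []
        for dy in range(-r, r + 1):
            yy = y + dy
            if not 0 <= yy < self.ny:
                continue
            for dx in range(-r, r + 1):
                xx = x + dx
                if not 0 <= xx < self.nx:
                    continue
                if dy * dy + dx * dx <= radius * radius and self.ocean[yy, xx]:
                    out.append((yy, xx))
        return out

    def nearest_suitable(self, y: float, x: float, sst_min: float) -> tuple[int, int]:
        """Centroid of the nearest ocean patch with SST >= sst_min."""
        ok = self.ocean & (self.SST >= sst_min)
        if not ok.any():
            ok = self.ocean
        ys, xs = np.nonzero(ok)
        i = int(np.argmin((ys - y) ** 2 + (xs - x) ** 2))
        return int(ys[i]), int(xs[i])


def synthetic_bathymetry(ny: int = 40, nx: int = 40) -> np.ndarray:
    """A deep basin with an eastern landmass fringed by a shallow shelf and
    a meridional shelf-edge corridor (-550 < depth < -50 m)."""
    depth = np.full((ny, nx), -2500.0)
    depth[:, nx - 3:] = 100.0          # land
    depth[:, nx - 6:nx - 3] = -120.0   # shallow shelf (nursery-able)
    depth[:, nx - 8:nx - 6] = -300.0   # shelf-edge corridor
    return depth


def read_raster_csv(path) -> np.ndarray:
    """Plain CSV raster (rows south->north, no header/index)."""
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def write_raster_csv(array: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(array)).to_csv(path, header=False, index=False)


def _load_bathymetry(source) -> np.ndarray:
    if isinstance(source, np.ndarray):
        return np.asarray(source, dtype=float)
    s = str(source)
    if s.endswith(".nc"):
        with xr.open_dataset(s) as ds:
            name = "depth" if "depth" in ds else list(ds.data_vars)[0]
            return ds[name].to_numpy().astype(float)
    return read_raster_csv(s)


def build_grid(spec: Mapping | None = None) -> Seascape:
    """Build a :class:`Seascape` from a grid configuration mapping.

    Recognized keys: ``ny``, ``nx``, ``cell_km``, ``lat0``, ``lon0``,
    ``bathymetry`` ('synthetic', a CSV/NetCDF path, or an array),
    ``nursery_max_lat``, ``nursery_meridian``, ``owarea_lat_min`` (or
    ``owarea_rect`` [y0, y1, x0, x1]), ``spawn_sector_max_lat``,
    ``spawn_dest``/``feed_dest`` as [y, x].
    """
    spec = dict(spec or {})
    ny = int(spec.get("ny", 40))
    nx = int(spec.get("nx", 40))
    cell_km = float(spec.get("cell_km", 60.0))
    lat0 = float(spec.get("lat0", 47.0))
    lon0 = float(spec.get("lon0", -45.0))

    bathy = spec.get("bathymetry", "synthetic")
    if isinstance(bathy, str) and bathy == "synthetic":
        depth = synthetic_bathymetry(ny, nx)
    else:
        depth = _load_bathymetry(bathy)
        ny, nx = depth.shape

    dlat = cell_km / KM_PER_DEG_LAT
    lat_rows = lat0 + (np.arange(ny) + 0.5) * dlat
    lat = np.repeat(lat_rows[:, None], nx, axis=1)
    lat_mid = lat_rows.mean()
    dlon = cell_km / (KM_PER_DEG_LAT * np.cos(np.deg2rad(lat_mid)))
    lon_cols = lon0 + (np.arange(nx) + 0.5) * dlon
    lon = np.repeat(lon_cols[None, :], ny, axis=0)

    sea = Seascape(depth=depth, lat=lat, lon=lon, cell_km=cell_km)

    # nursery: shallow (>= -200 m) patches, optionally west of a meridian,
    # in the southern part of the grid
    nursery_max_lat = float(spec.get("nursery_max_lat", lat_rows[0] + 0.3 * (lat_rows[-1] - lat_rows[0])))
    meridian = spec.get("nursery_meridian")
    sea.narea = sea.ocean & (sea.depth >= -200.0) & (lat <= nursery_max_lat)
    if meridian is not None:
        sea.narea &= lon < float(meridian)
    if not sea.narea.any():
        raise SeascapeError("nursery area is empty for this configuration")

    # overwintering area: configurable rectangle set; synthetic default is
    # the shelf-depth band at the northern end of the corridor
    if "owarea_rect" in spec:
        y0, y1, x0, x1 = (int(v) for v in spec["owarea_rect"])
        sea.owarea[y0:y1, x0:x1] = True
        sea.owarea &= sea.ocean
    else:
        ow_lat_min = float(spec.get("owarea_lat_min", lat_rows[0] + 0.72 * (lat_rows[-1] - lat_rows[0])))
        sea.owarea = sea.ocean & (sea.depth > -550.0) & (lat >= ow_lat_min)
    if not sea.owarea.any():
        raise SeascapeError("overwintering area is empty for this configuration")

    sea.spawn_sector_max_lat = float(
        spec.get("spawn_sector_max_lat", lat_rows[0] + 0.5 * (lat_rows[-1] - lat_rows[0]))
    )

    # destination patches: configuration entries; synthetic defaults sit at
    # the southern end (spawning) and northern exit (feeding/overwintering)
    # of the shelf-edge corridor
    se_y, se_x = np.nonzero(sea.shelf_edge)
    if se_y.size == 0:
        raise SeascapeError("no shelf-edge patches on this grid")
    if "spawn_dest" in spec:
        sea.spawn_dest = tuple(int(v) for v in spec["spawn_dest"])
    else:
        y_min = se_y.min()
        sea.spawn_dest = (int(y_min), int(np.median(se_x[se_y == y_min])))
    if "feed_dest" in spec:
        sea.feed_dest = tuple(int(v) for v in spec["feed_dest"])
    else:
        y_max = se_y.max()
        sea.feed_dest = (int(y_max), int(np.median(se_x[se_y == y_max])))
    for name, dest in (("spawn_dest", sea.spawn_dest), ("feed_dest", sea.feed_dest)):
        if not sea.is_ocean(*dest):
            raise SeascapeError(f"{name} {dest} is on land")

    sea.spawn_dist = distance_field(sea, sea.spawn_dest)
    sea.feed_dist = distance_field(sea, sea.feed_dest)
    return sea


def distance_field(sea: Seascape, destination: tuple[int, int]) -> np.ndarray:
    """Breadth-first-search hop count from every ocean patch to the
    destination, with land impassable (4-neighbour adjacency).

    Land patches carry ``LAND`` and ocean patches the destination cannot
    reach carry ``UNREACHABLE``.
    """
    dy0, dx0 = destination
    if not sea.is_ocean(dy0, dx0):
        raise SeascapeError(f"destination {destination} is not an ocean patch")
    R = np.full((sea.ny, sea.nx), UNREACHABLE, dtype=np.int32)
    R[~sea.ocean] = LAND
    R[dy0, dx0] = 0
    q = deque([(dy0, dx0)])
    while q:
        y, x = q.popleft()
        r1 = R[y, x] + 1
        for dy, dx in NEIGHBOURS_4:
            yy, xx = y + dy, x + dx
            if 0 <= yy < sea.ny and 0 <= xx < sea.nx and R[yy, xx] == UNREACHABLE:
                R[yy, xx] = r1
                q.append((yy, xx))
    return R


def spawning_mask(sea: Seascape) -> np.ndarray:
    """Shelf-edge patches in the spawning sector with 10 < SST < 14 degC
    (strict inequalities).  Recomputed whenever SST updates."""
    mask = sea.shelf_edge & (sea.SST > 10.0) & (sea.SST < 14.0)
    if sea.spawn_sector_max_lat is not None:
        mask &= sea.lat <= sea.spawn_sector_max_lat
    sea.sarea = mask
    return mask


# ---------------------------------------------------------------------------
# photoperiod
# ---------------------------------------------------------------------------

def daylength_fraction(lat_deg: np.ndarray, doy: int) -> np.ndarray:
    """Daylength as a fraction of 24 h (CBM model of Forsythe et al. 1995)."""
    lat = np.asarray(lat_deg, dtype=float)
    theta = 0.2163108 + 2.0 * np.arctan(
        0.9671396 * np.tan(0.00860 * (doy - 186.0))
    )
    phi = np.arcsin(0.39795 * np.cos(theta))  # solar declination, radians
    arg = (
        np.sin(np.deg2rad(0.8333)) + np.sin(np.deg2rad(lat)) * np.sin(phi)
    ) / (np.cos(np.deg2rad(lat)) * np.cos(phi))
    arg = np.clip(arg, -1.0, 1.0)
    hours = 24.0 - (24.0 / np.pi) * np.arccos(arg)
    return hours / 24.0


# ---------------------------------------------------------------------------
# synthetic forcing
# ---------------------------------------------------------------------------

COMPOSITES_PER_YEAR = 37  # ten-day composites (last covers days 361-365)


@dataclass
class Forcing:
    """Time-indexed field stacks with per-variable update cadence:
    X and SST every 10 days; U, V and photoperiod monthly."""

    year0: int
    n_years: int
    X: np.ndarray        # (n_years * 37, ny, nx)
    SST: np.ndarray      # (n_years * 37, ny, nx)
    U: np.ndarray        # (n_years * 12, ny, nx)
    V: np.ndarray        # (n_years * 12, ny, nx)
    p_photo: np.ndarray  # (12, ny, nx) monthly climatology, 15th of month

    def covers(self, year: int) -> bool:
        return self.year0 <= year < self.year0 + self.n_years

    def _check(self, year: int) -> None:
        if not self.covers(year):
            raise SeascapeError(
                f"forcing covers {self.year0}..{self.year0 + self.n_years - 1}; "
                f"requested year {year}"
            )

    def composite(self, year: int, doy: int) -> int:
        self._check(year)
        return (year - self.year0) * COMPOSITES_PER_YEAR + (doy - 1) // 10

    def month_index(self, year: int, month: int) -> int:
        self._check(year)
        return (year - self.year0) * 12 + (month - 1)


def generate_synthetic_forcing(
    sea: Seascape, spec: Mapping | None = None, seed: int = 0
) -> Forcing:
    """Deterministic synthetic forcing emulating the stock's seascape.

    The SST field carries a meridional gradient plus a seasonal cycle so a
    10-14 degC band opens in the south in early spring and progresses
    northward (exercising spawning movement), and the far north dips below
    7 degC outside high summer (exercising cold avoidance).  The plankton
    bloom peaks in summer, stronger and later at high latitude, so the
    northward feeding migration is rewarded.  Currents are weak and steady.
    """
    spec = dict(spec or {})
    year0 = int(spec.get("year0", 2000))
    n_years = int(spec.get("n_years", 5))
    bloom_amplitude = float(spec.get("bloom_amplitude", 2.5))   # g m-2
    if bloom_amplitude <= 0:
        raise SeascapeError("bloom amplitude must be positive")
    bloom_base = float(spec.get("bloom_base", 0.3))             # g m-2
    bloom_width = float(spec.get("bloom_width_days", 45.0))
    bloom_peak_doy = float(spec.get("bloom_peak_doy", 150.0))   # at lat0
    bloom_peak_lat_shift = float(spec.get("bloom_peak_lat_shift", 2.0))
    sst_south = float(spec.get("sst_south", 15.0))              # degC
    sst_gradient = float(spec.get("sst_gradient", 0.5))         # degC per deg lat
    sst_amp = float(spec.get("sst_season_amp", 4.0))
    sst_peak_doy = float(spec.get("sst_peak_doy", 213.0))       # Aug 1
    cur_u = float(spec.get("current_u", 0.05))                  # km h-1
    cur_v = float(spec.get("current_v", 0.03))
    noise_sd = float(spec.get("noise_sd", 0.05))

    rng = np.random.default_rng(seed)
    ny, nx = sea.ny, sea.nx
    lat = sea.lat
    lat0 = float(lat.min())

    nc = n_years * COMPOSITES_PER_YEAR
    X = np.empty((nc, ny, nx))
    SST = np.empty((nc, ny, nx))
    for i in range(nc):
        doy = (i % COMPOSITES_PER_YEAR) * 10 + 5.0  # composite mid-date
        sst = (
            sst_south
            - sst_gradient * (lat - lat0)
            + sst_amp * np.cos(2.0 * np.pi * (doy - sst_peak_doy) / DAYS_PER_YEAR)
        )
        sst = sst + noise_sd * rng.standard_normal((ny, nx))
        peak = bloom_peak_doy + bloom_peak_lat_shift * (lat - lat0)
        latfac = 0.5 + 0.5 * (lat - lat0) / max(lat.max() - lat0, 1e-9)
        x = bloom_base + bloom_amplitude * latfac * np.exp(
            -(((doy - peak) / bloom_width) ** 2)
        )
        x = x * np.exp(noise_sd * rng.standard_normal((ny, nx)))
        SST[i] = sst
        X[i] = np.maximum(x, 0.0)

    nm = n_years * 12
    U = np.empty((nm, ny, nx))
    V = np.empty((nm, ny, nx))
    for j in range(nm):
        U[j] = cur_u + 0.2 * cur_u * rng.standard_normal((ny, nx))
        V[j] = cur_v + 0.2 * cur_v * rng.standard_normal((ny, nx))

    p_photo = np.empty((12, ny, nx))
    for m in range(12):
        doy15 = MONTH_STARTS[m] + 14
        p_photo[m] = daylength_fraction(lat, doy15)

    return Forcing(year0=year0, n_years=n_years, X=X, SST=SST, U=U, V=V,
                   p_photo=p_photo)


def write_forcing_netcdf(forcing: Forcing, path) -> None:
    """Persist a forcing stack as NetCDF-3 (composite and monthly axes)."""
    ds = xr.Dataset(
        {
            "X": (("composite", "y", "x"), forcing.X),
            "SST": (("composite", "y", "x"), forcing.SST),
            "U": (("month", "y", "x"), forcing.U),
            "V": (("month", "y", "x"), forcing.V),
            "p_photo": (("climatology_month", "y", "x"), forcing.p_photo),
        },
        attrs={"year0": forcing.year0, "n_years": forcing.n_years},
    )
    ds.to_netcdf(path, engine="scipy")


def load_forcing_netcdf(path) -> Forcing:
    """Read a forcing stack written by :func:`write_forcing_netcdf` (or any
    NetCDF with the same variable names and axes)."""
    with xr.open_dataset(path) as ds:
        return Forcing(
            year0=int(ds.attrs["year0"]),
            n_years=int(ds.attrs["n_years"]),
            X=ds["X"].to_numpy(),
            SST=ds["SST"].to_numpy(),
            U=ds["U"].to_numpy(),
            V=ds["V"].to_numpy(),
            p_photo=ds["p_photo"].to_numpy(),
        )


def update_forcing(sea: Seascape, forcing: Forcing, year: int, doy: int) -> Seascape:
    """Refresh the seascape's fields for calendar day ``doy`` of ``year``.

    X and SST refresh on 10-day composite boundaries (days 1, 11, 21, ...);
    photoperiod and currents refresh at the start of each month (photoperiod
    values correspond to the 15th day of the month).  The spawning-area mask
    is recomputed whenever SST changes.
    """
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise SeascapeError(f"day of year {doy} outside 1..{DAYS_PER_YEAR}")
    forcing._check(year)
    if (doy - 1) % 10 == 0:
        i = forcing.composite(year, doy)
        sea.X = forcing.X[i].copy()
        sea.SST = forcing.SST[i].copy()
        spawning_mask(sea)
    if doy in MONTH_STARTS:
        month = month_of_doy(doy)
        j = forcing.month_index(year, month)
        sea.U = forcing.U[j].copy()
        sea.V = forcing.V[j].copy()
        sea.p_photo = forcing.p_photo[month - 1].copy()
    return sea
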