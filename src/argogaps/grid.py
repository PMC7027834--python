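"""Global 1-degree analysis lattice: cell geometry, spherical areas, static masks.

All analysis rasters in this package are 2-D numpy arrays of shape
``(n_lat, n_lon)`` with rows running south to north (row 0 is the band
[-90, -89)) and columns west to east (column 0 is [-180, -179)).  Areas are
computed analytically on the sphere, so any partition of the grid sums
exactly (to floating tolerance) to the global surface; an equal-area map
projection is used only for rendering, never for accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Latitudinal ocean sectors delimited by the 30th and 60th parallels.
SECTOR_NAMES = ("Antarctic", "Southern", "Tropical", "Northern", "Arctic")

#: Default bathymetry class breaks in metres (right-open bins).
DEFAULT_DEPTH_BREAKS = (200.0, 1000.0, 2000.0)

DEPTH_CLASS_NAMES = ("0-200m", "200-1000m", "1000-2000m", ">2000m")


@dataclass(frozen=True)
class GlobalGrid:
    """The canonical 1°x1° global lattice (180 rows x 360 columns).

    Cells are half-open ``[lo, hi)`` in both axes; the single point lat=90
    is assigned to the northernmost band.  Longitudes wrap modulo 360.
    """

    n_lat: int = 180
    n_lon: int = 360
    radius_km: float = EARTH_RADIUS_KM

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def size(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lat_edges(self) -> np.ndarray:
        return np.linspace(-90.0, 90.0, self.n_lat + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return np.linspace(-180.0, 180.0, self.n_lon + 1)

    @property
    def lat_centers(self) -> np.ndarray:
        e = self.lat_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        e = self.lon_edges
        return 0.5 * (e[:-1] + e[1:])

    def normalize_lon(self, lon):
        """Wrap longitudes into [-180, 180)."""
        return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0

    def cell_of(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices.

        Raises ``ValueError`` for latitudes outside [-90, 90].  lat=90 is
        clamped into the top band; longitudes wrap.
        """
        lat = np.asarray(lat, dtype=float)
        lon = self.normalize_lon(lon)
        if np.any((lat < -90.0) | (lat > 90.0) | ~np.isfinite(lat)):
            raise ValueError("latitude outside [-90, 90]")
        dlat = 180.0 / self.n_lat
        dlon = 360.0 / self.n_lon
        row = np.minimum(np.floor((lat + 90.0) / dlat).astype(int), self.n_lat - 1)
        col = np.floor((lon + 180.0) / dlon).astype(int) % self.n_lon
        return row, col


def make_grid() -> GlobalGrid:
    """Return the canonical global 1° lattice."""
    return GlobalGrid()


def cell_areas(grid: GlobalGrid) -> np.ndarray:
    """Exact spherical cell areas in km², shape ``grid.shape``.

    The area of a cell in the latitude band [phi1, phi2] with width dlon
    degrees is ``R² · deg2rad(dlon) · (sin phi2 − sin phi1)``: the classic
    spherical-zone formula.  Areas depend only on the latitude row and sum
    to 4πR² over the globe.
    """
    edges = np.deg2rad(grid.lat_edges)
    dlon = np.deg2rad(360.0 / grid.n_lon)
    band = grid.radius_km**2 * dlon * (np.sin(edges[1:]) - np.sin(edges[:-1]))
    return np.repeat(band[:, None], grid.n_lon, axis=1)


def sector_masks(grid: GlobalGrid) -> np.ndarray:
    """Sector id per cell (0..4 indexing :data:`SECTOR_NAMES`).

    Cells are assigned by center latitude to the five bands
    [-90,-60), [-60,-30), [-30,30), [30,60), [60,90].
    """
    edges = np.array([-60.0, -30.0, 30.0, 60.0])
    sec = np.searchsorted(edges, grid.lat_centers, side="right")
    return np.repeat(sec[:, None], grid.n_lon, axis=1).astype(np.int8)


def classify_bathymetry(depth_m: np.ndarray,
                        breaks: Sequence[float] = DEFAULT_DEPTH_BREAKS) -> np.ndarray:
    """Classify depths into half-open bins [0,200), [200,1000), [1000,2000), [2000,inf).

    A boundary depth belongs to the higher class.  NaN depths (land) map to -1.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.ndim != 1 or len(breaks) == 0 or np.any(np.diff(breaks) <= 0):
        raise ValueError("bathymetry breaks must be strictly increasing")
    depth_m = np.asarray(depth_m, dtype=float)
    cls = np.searchsorted(breaks, depth_m, side="right").astype(np.int8)
    cls[~np.isfinite(depth_m)] = -1
    return cls


def zonal_fraction(value_mask: np.ndarray, zones: np.ndarray, areas: np.ndarray,
                   zone_names: dict | None = None) -> pd.DataFrame:
    """Area of the true cells of ``value_mask`` per zone, and its fraction
    of the total true area.

    Fractions sum to 1 when the mask is non-empty; an empty mask yields all
    fractions 0 (no division is attempted).  Zones with negative ids
    (e.g. land sentinel -1) are excluded.
    """
    value_mask = np.asarray(value_mask, dtype=bool)
    zones = np.asarray(zones)
    areas = np.asarray(areas, dtype=float)
    if not (value_mask.shape == zones.shape == areas.shape):
        raise ValueError("raster shapes do not match")
    ids = np.unique(zones[zones >= 0])
    rows = []
    total = float(areas[value_mask].sum())
    for z in ids:
        a = float(areas[value_mask & (zones == z)].sum())
        frac = a / total if total > 0 else 0.0
        name = zone_names.get(int(z), int(z)) if zone_names else int(z)
        rows.append({"zone": name, "area_km2": a, "fraction": frac})
    return pd.DataFrame(rows, columns=["zone", "area_km2", "fraction"])


@dataclass
class StaticMasks:
    """Static world layers on the analysis grid.

    ocean      boolean per cell
    depth_m    bathymetry in metres; >=0 on ocean cells, NaN on land
    eez_id     integer per cell, 0 = high seas / land
    sector_id  0..4 per cell (see :data:`SECTOR_NAMES`)
    """

    ocean: np.ndarray
    depth_m: np.ndarray
    eez_id: np.ndarray
    sector_id: np.ndarray

    def __post_init__(self):
        shp = self.ocean.shape
        for name in ("depth_m", "eez_id", "sector_id"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shp}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ocean.shape
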