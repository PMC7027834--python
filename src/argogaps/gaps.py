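"""Observing-network gap analysis: annual profile density, gap classification,
multi-year persistence, and coherent coldspot extraction.

A cell-year is a sampling *gap* if it is un-sampled (zero profiles) or
under-sampled (a positive count strictly below the lowest quintile of the
strictly positive counts over ocean cells that year).  *Persistence* is the
fraction of analysed years a cell was a gap.  *Coldspots* are connected
components of cells with persistence >= 0.8 spanning at least 25 one-degree
cells, labelled with longitude wrap-around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GlobalGrid, StaticMasks, zonal_fraction, classify_bathymetry, \
    DEPTH_CLASS_NAMES, SECTOR_NAMES, DEFAULT_DEPTH_BREAKS

log = logging.getLogger(__name__)

#: Analysis period of the reference study.
DEFAULT_YEARS = tuple(range(2005, 2017))


@dataclass
class AnnualDensity:
    """Profile counts per grid cell for one calendar year."""

    year: int
    counts: np.ndarray  # non-negative int, grid shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class GapStack:
    """Boolean gap rasters per year plus the derived persistence raster."""

    years: tuple[int, ...]
    gap: np.ndarray  # (n_years, n_lat, n_lon) bool

    def __post_init__(self):
        if len(self.years) == 0:
            raise ValueError("GapStack needs at least one year")
        if self.gap.shape[0] != len(self.years):
            raise ValueError("gap raster count does not match years")

    @property
    def persistence(self) -> np.ndarray:
        return persistence(self)


@dataclass
class ColdspotMap:
    """Labelled coherent gap components.

    ``labels`` is 0 for background, 1..K for components in decreasing area
    order.  ``table`` has one row per component: label, n_cells, area_km2
    (NaN if no area map was supplied at extraction time).
    """

    labels: np.ndarray
    table: pd.DataFrame

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_components(self) -> int:
        return len(self.table)


def bin_profiles(profiles: pd.DataFrame, grid: GlobalGrid, year: int) -> AnnualDensity:
    """Bin profile positions of one calendar year onto the grid.

    ``profiles`` needs columns ``timestamp`` (datetime-like or parseable),
    ``lat`` and ``lon``.  Rows with unparseable timestamps are skipped and
    rows with |lat| > 90 rejected; both are counted and logged.  Profiles
    dated outside ``year`` are silently ignored (they belong to other bins).
    """
    ts = pd.to_datetime(profiles["timestamp"], errors="coerce", format="mixed")
    bad_ts = ts.isna()
    if bad_ts.any():
        log.warning("bin_profiles: skipped %d rows with unparseable timestamps",
                    int(bad_ts.sum()))
    lat = pd.to_numeric(profiles["lat"], errors="coerce")
    lon = pd.to_numeric(profiles["lon"], errors="coerce")
    bad_pos = lat.isna() | lon.isna() | (lat < -90) | (lat > 90) | ~np.isfinite(lon)
    if (bad_pos & ~bad_ts).any():
        log.warning("bin_profiles: rejected %d rows with invalid positions",
                    int((bad_pos & ~bad_ts).sum()))
    keep = ~bad_ts & ~bad_pos & (ts.dt.year == year)
    counts = np.zeros(grid.shape, dtype=np.int64)
    if keep.any():
        row, col = grid.cell_of(lat[keep].to_numpy(), lon[keep].to_numpy())
        np.add.at(counts, (row, col), 1)
    return AnnualDensity(year=year, counts=counts)


def annual_gap_mask(density: AnnualDensity | np.ndarray, ocean: np.ndarray,
                    q: float = 0.20) -> np.ndarray:
    """Classify one year's sampling gaps.

    A gap is an ocean cell that is either un-sampled (count 0) or
    under-sampled: its positive count is strictly below the empirical
    q-quantile (linear interpolation) of the strictly positive counts over
    ocean cells of that year.  Zero-count cells never enter the quantile.
    """
    if not 0 < q < 1:
        raise ValueError("quantile q must be in (0, 1)")
    counts = density.counts if isinstance(density, AnnualDensity) else np.asarray(density)
    ocean = np.asarray(ocean, dtype=bool)
    if counts.shape != ocean.shape:
        raise ValueError("raster shapes do not match")
    if not ocean.any():
        raise ValueError("ocean mask is empty")
    pos = counts[ocean & (counts > 0)]
    gap = ocean & (counts == 0)
    if pos.size:
        thr = np.quantile(pos, q)  # linear interpolation
        gap |= ocean & (counts > 0) & (counts < thr)
    return gap


def build_gap_stack(densities: list[AnnualDensity], ocean: np.ndarray,
                    q: float = 0.20) -> GapStack:
    """Apply :func:`annual_gap_mask` year by year (the quintile is per-year)."""
    years = tuple(d.year for d in densities)
    gap = np.stack([annual_gap_mask(d, ocean, q=q) for d in densities])
    return GapStack(years=years, gap=gap)


def persistence(stack: GapStack) -> np.ndarray:
    """Fraction of analysed years each cell was flagged as gap.

    The denominator is the number of analysed years, so values are exact
    multiples of 1/n_years.  Non-ocean cells are never flagged, hence 0.
    """
    n = len(stack.years)
    return stack.gap.sum(axis=0) / float(n)


def _label_wrapped(binary: np.ndarray, connectivity: int, wrap: bool) -> np.ndarray:
    """Connected-component labels with optional east-west wrap-around."""
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(binary, structure=structure)
    if wrap and n > 1 and binary.shape[1] > 1:
        # union-find over label pairs adjacent across the seam
        parent = np.arange(n + 1)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        left, right = labels[:, 0], labels[:, -1]
        nrow = binary.shape[0]
        for r in range(nrow):
            if not right[r]:
                continue
            rows = (r,) if connectivity == 4 else (r - 1, r, r + 1)
            for rr in rows:
                if 0 <= rr < nrow and left[rr]:
                    a, b = find(right[r]), find(left[rr])
                    if a != b:
                        parent[max(a, b)] = min(a, b)
        roots = np.array([find(i) for i in range(n + 1)])
        labels = roots[labels]
    return labels


def extract_coldspots(persistence_raster: np.ndarray, threshold: float = 0.8,
                      min_cells: int = 25, connectivity: int = 8,
                      wrap: bool = True, areas: np.ndarray | None = None) -> ColdspotMap:
    """Extract coherent coldspots from a persistence raster.

    Cells with persistence >= ``threshold`` are binarized, connected
    components are labelled (8-connectivity by default, with column 0
    adjacent to the last column when ``wrap``), components smaller than
    ``min_cells`` cells are dropped, and survivors are relabelled 1..K in
    decreasing area order (cell count when no area map is given).
    """
    pers = np.asarray(persistence_raster, dtype=float)
    if np.any((pers < 0) | (pers > 1)):
        raise ValueError("persistence values must lie in [0, 1]")
    binary = pers >= threshold
    labels = _label_wrapped(binary, connectivity, wrap)
    ids = np.unique(labels[labels > 0])
    comps = []
    for i in ids:
        m = labels == i
        ncell = int(m.sum())
        if ncell < min_cells:
            continue
        area = float(areas[m].sum()) if areas is not None else np.nan
        comps.append((int(i), ncell, area))
    key = (lambda c: (-c[2], c[0])) if areas is not None else (lambda c: (-c[1], c[0]))
    comps.sort(key=key)
    out = np.zeros_like(labels)
    rows = []
    for newlab, (old, ncell, area) in enumerate(comps, start=1):
        out[labels == old] = newlab
        rows.append({"label": newlab, "n_cells": ncell, "area_km2": area})
    table = pd.DataFrame(rows, columns=["label", "n_cells", "area_km2"])
    return ColdspotMap(labels=out, table=table)


def coldspot_summary(cmap: ColdspotMap, masks: StaticMasks, areas: np.ndarray,
                     depth_breaks=DEFAULT_DEPTH_BREAKS) -> dict:
    """Summaries of the coldspot surface by sector, bathymetry and EEZ.

    Returns a dict with total area, the ocean fraction it represents,
    per-sector / per-depth-class fraction tables, the fraction of coldspot
    surface inside any EEZ, a per-EEZ area ranking, and the fraction
    poleward of 60° (Antarctic + Arctic sectors).
    """
    mask = cmap.mask
    if mask.shape != masks.shape or mask.shape != areas.shape:
        raise ValueError("raster shapes do not match")
    total = float(areas[mask].sum())
    ocean_area = float(areas[masks.ocean].sum())

    sector_tab = zonal_fraction(mask, masks.sector_id, areas,
                                zone_names=dict(enumerate(SECTOR_NAMES)))
    depth_cls = classify_bathymetry(masks.depth_m, depth_breaks)
    depth_tab = zonal_fraction(mask & masks.ocean, depth_cls, areas,
                               zone_names=dict(enumerate(DEPTH_CLASS_NAMES)))
    polar = sector_tab.loc[sector_tab["zone"].isin(["Antarctic", "Arctic"]),
                           "fraction"].sum()

    eez_area = float(areas[mask & (masks.eez_id != 0)].sum())
    eez_fraction = eez_area / total if total > 0 else 0.0
    in_eez = mask & (masks.eez_id != 0)
    eez_rank = zonal_fraction(in_eez, masks.eez_id, areas)
    eez_rank = eez_rank[eez_rank["zone"] != 0].sort_values(
        "area_km2", ascending=False).reset_index(drop=True)

    return {
        "total_area_km2": total,
        "ocean_fraction": total / ocean_area if ocean_area > 0 else 0.0,
        "by_sector": sector_tab,
        "by_depth_class": depth_tab,
        "poleward_60_fraction": float(polar),
        "eez_fraction": eez_fraction,
        "eez_ranking": eez_rank,
    }
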