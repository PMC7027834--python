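"""Gridding of animal telemetry locations and their three-way overlap with
coldspots and EOO ranges.

Telemetry points (pinnipeds and sea turtles carry most oceanographic tags)
are binned to the analysis grid; coldspot cells are then classified by
whether overlap is supported by direct observations, by the EOO envelope
only, or by neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaps import ColdspotMap
from .grid import GlobalGrid, EARTH_RADIUS_KM

log = logging.getLogger(__name__)

TRISTATE_NAMES = {0: "neither", 1: "eoo_only", 2: "telemetry_and_eoo"}


@dataclass
class TelemetryGrid:
    """Per-cell telemetry location counts; presence means count above threshold."""

    count: np.ndarray
    min_count: int = 1

    @property
    def presence(self) -> np.ndarray:
        return self.count >= self.min_count

    @property
    def total(self) -> int:
        return int(self.count.sum())


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between coordinate arrays (degrees)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(np.asarray(lon2, float) - np.asarray(lon1, float))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * radius_km * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def speed_filter(points: pd.DataFrame, vmax_kmh: float = np.inf,
                 enabled: bool = False) -> pd.DataFrame:
    """Drop implausibly fast locations from one animal's track.

    Iteratively removes points whose great-circle speed from the previous
    *retained* point exceeds ``vmax_kmh``.  Disabled by default: public
    telemetry compilations are typically already quality-controlled, and
    silent filtering hurts reproducibility.  Timestamps must be sorted.
    """
    if not enabled or len(points) <= 1 or not np.isfinite(vmax_kmh):
        if len(points) > 1:
            ts = pd.to_datetime(points["timestamp"])
            if not ts.is_monotonic_increasing:
                raise ValueError("speed_filter requires time-sorted points")
        return points
    ts = pd.to_datetime(points["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("speed_filter requires time-sorted points")
    lat = points["lat"].to_numpy(float)
    lon = points["lon"].to_numpy(float)
    tsec = ts.astype("int64").to_numpy() / 1e9
    keep = [0]
    for i in range(1, len(points)):
        j = keep[-1]
        dt_h = (tsec[i] - tsec[j]) / 3600.0
        d = float(haversine_km(lat[j], lon[j], lat[i], lon[i]))
        if dt_h <= 0 or d / dt_h > vmax_kmh:
            continue
        keep.append(i)
    dropped = len(points) - len(keep)
    if dropped:
        log.info("speed_filter: dropped %d of %d points (> %.1f km/h)",
                 dropped, len(points), vmax_kmh)
    return points.iloc[keep]


def grid_telemetry(points: pd.DataFrame, grid: GlobalGrid,
                   min_count: int = 1) -> TelemetryGrid:
    """Bin telemetry locations of any number of animals onto the grid."""
    count = np.zeros(grid.shape, dtype=np.int64)
    if len(points):
        row, col = grid.cell_of(points["lat"].to_numpy(float),
                                points["lon"].to_numpy(float))
        np.add.at(count, (row, col), 1)
    return TelemetryGrid(count=count, min_count=min_count)


def tristate_overlap(telemetry: TelemetryGrid, eoo_presence: np.ndarray,
                     cmap: ColdspotMap, areas: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify coldspot cells by observational support.

    Within the coldspot mask: class 2 where telemetry and the EOO envelope
    agree, class 1 where only the EOO covers the cell, class 0 where
    neither does.  Non-coldspot cells are -1.  The three class areas
    partition the coldspot area exactly.  Telemetry outside the EOO is
    retained (EOO maps can be incomplete) but logged.
    """
    eoo = np.asarray(eoo_presence, dtype=bool)
    cold = cmap.mask
    if eoo.shape != cold.shape or eoo.shape != np.asarray(areas).shape:
        raise ValueError("raster shapes do not match")
    tel = telemetry.presence
    outside = int((tel & ~eoo).sum())
    if outside:
        log.info("tristate_overlap: telemetry present in %d cells outside the EOO", outside)
    classes = np.full(cold.shape, -1, dtype=np.int8)
    classes[cold] = 0
    classes[cold & eoo] = 1
    classes[cold & eoo & tel] = 2
    rows = []
    for k, name in TRISTATE_NAMES.items():
        m = classes == k
        rows.append({"class": name,
                     "n_cells": int(m.sum()),
                     "area_km2": float(np.asarray(areas)[m].sum())})
    return classes, pd.DataFrame(rows)
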