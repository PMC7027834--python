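"""Species distribution layers: EOO rasterization, richness, normalized
composite, range areas and dive-depth strata.

Extent-of-occurrence (EOO) polygons are coarse envelopes of where a species
is known to occur; rasterization is deliberately inclusive (a cell is
present if the polygon overlaps it with positive area) and restricted to
ocean cells.  Richness per taxon is rescaled to [0, 1] by its global
maximum, and the cross-taxon composite is the unweighted cell-wise mean of
the eight normalized layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import GlobalGrid

#: The eight taxonomic groups of instrumentable marine vertebrates.
TAXA = (
    "tuna_billfishes",
    "sharks_rays",
    "pinnipeds",
    "cetaceans",
    "penguins",
    "flying_seabirds",
    "turtles",
    "sirenians",
)

DEPTH_STRATA = ("epipelagic_le_200", "meso_200_1000", "deep_1000_2000",
                "gt_2000", "unknown")


@dataclass
class SpeciesEntry:
    """One species: identity, taxon, maximum dive depth and its range."""

    species_id: str
    name: str
    taxon: str
    max_dive_depth_m: float | None = None  # None/NaN = unknown, distinct from 0
    eoo: BaseGeometry | np.ndarray | None = None

    def __post_init__(self):
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}")


@dataclass
class RichnessLayer:
    """Per-taxon species richness and its [0, 1] rescaling."""

    taxon: str
    count: np.ndarray
    normalized: np.ndarray


@dataclass
class CompositeLayer:
    """Cross-taxon mean of the eight normalized richness layers."""

    value: np.ndarray


def rasterize_eoo(eoo: BaseGeometry, grid: GlobalGrid,
                  ocean: np.ndarray | None = None,
                  species: str | None = None) -> np.ndarray:
    """Rasterize an EOO polygon set to a boolean presence raster.

    A cell is present iff the geometry intersects the cell rectangle with
    positive area (a shared edge does not count), then presence is
    restricted to ocean cells if a mask is given.  Self-intersecting input
    is repaired with ``shapely.make_valid``; empty or unrepairable geometry
    raises ``ValueError`` naming the species.
    """
    who = f" for species {species!r}" if species else ""
    if eoo is None or not isinstance(eoo, BaseGeometry) or eoo.is_empty:
        raise ValueError(f"empty EOO geometry{who}")
    if not eoo.is_valid:
        eoo = shapely.make_valid(eoo)
        if eoo.is_empty:
            raise ValueError(f"invalid EOO geometry{who}")
    minx, miny, maxx, maxy = eoo.bounds
    if minx < -180.0 - 1e-9 or maxx > 180.0 + 1e-9:
        raise ValueError(f"EOO longitudes outside [-180, 180]{who}")
    lat_e, lon_e = grid.lat_edges, grid.lon_edges
    r0 = int(np.clip(np.searchsorted(lat_e, miny, "right") - 1, 0, grid.n_lat - 1))
    r1 = int(np.clip(np.searchsorted(lat_e, maxy, "left"), 1, grid.n_lat))
    c0 = int(np.clip(np.searchsorted(lon_e, minx, "right") - 1, 0, grid.n_lon - 1))
    c1 = int(np.clip(np.searchsorted(lon_e, maxx, "left"), 1, grid.n_lon))
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    cc, rr = np.meshgrid(cols, rows)
    boxes = shapely.box(lon_e[cc].ravel(), lat_e[rr].ravel(),
                        lon_e[cc + 1].ravel(), lat_e[rr + 1].ravel())
    inter = shapely.area(shapely.intersection(eoo, boxes)) > 0
    present = np.zeros(grid.shape, dtype=bool)
    present[rr.ravel(), cc.ravel()] = inter
    if ocean is not None:
        present &= np.asarray(ocean, dtype=bool)
    return present


def range_area(presence: np.ndarray, areas: np.ndarray) -> float:
    """Total range surface in km²: sum of cell areas where present."""
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != np.asarray(areas).shape:
        raise ValueError("raster shapes do not match")
    return float(np.asarray(areas)[presence].sum())


def taxon_richness(presences: list[np.ndarray], taxon: str,
                   taxa: list[str] | None = None) -> RichnessLayer:
    """Cell-wise species count for one taxon, rescaled to [0, 1].

    ``normalized = count / max(count)`` when the maximum is positive, else
    all zeros (no division by zero).  If per-raster taxa are supplied they
    must all equal ``taxon``.
    """
    if len(presences) == 0:
        raise ValueError("taxon_richness needs at least one species")
    if taxa is not None and any(t != taxon for t in taxa):
        raise ValueError(f"mixed taxa passed to taxon_richness({taxon!r})")
    count = np.zeros(np.asarray(presences[0]).shape, dtype=np.int32)
    for p in presences:
        count += np.asarray(p, dtype=bool)
    mx = int(count.max())
    normalized = count / mx if mx > 0 else np.zeros(count.shape, dtype=float)
    return RichnessLayer(taxon=taxon, count=count, normalized=np.asarray(normalized, float))


def composite(layers: dict[str, RichnessLayer] | list[RichnessLayer],
              mode: str = "all_taxa") -> CompositeLayer:
    """Cross-taxon composite of the eight normalized richness layers.

    Default ``all_taxa`` mode is the unweighted cell-wise mean over all
    eight taxa, zeros included.  ``present_taxa`` averages only over taxa
    with nonzero richness at each cell (offered as an alternative reading,
    not the default).  Exactly one layer per taxon is required.
    """
    if isinstance(layers, dict):
        layer_map = layers
    else:
        layer_map = {l.taxon: l for l in layers}
    missing = [t for t in TAXA if t not in layer_map]
    if missing or len(layer_map) != len(TAXA):
        raise ValueError(f"composite needs exactly one layer per taxon; missing {missing}")
    stack = np.stack([layer_map[t].normalized for t in TAXA])
    if mode == "all_taxa":
        value = stack.mean(axis=0)
    elif mode == "present_taxa":
        npresent = (stack > 0).sum(axis=0)
        value = np.where(npresent > 0, stack.sum(axis=0) / np.maximum(npresent, 1), 0.0)
    else:
        raise ValueError(f"unknown composite mode {mode!r}")
    return CompositeLayer(value=value)


def depth_stratum(max_dive_depth_m: float | None) -> str:
    """Assign a maximum dive depth to a vertical stratum.

    Bins are right-closed: (0,200] epipelagic, (200,1000] mesopelagic
    reach, (1000,2000], (2000,inf).  Missing depth maps to ``unknown`` and
    is excluded from stratum-proportion denominators.
    """
    d = max_dive_depth_m
    if d is None or (isinstance(d, float) and math.isnan(d)):
        return "unknown"
    d = float(d)
    if d < 0:
        raise ValueError("maximum dive depth cannot be negative")
    if d <= 200:
        return "epipelagic_le_200"
    if d <= 1000:
        return "meso_200_1000"
    if d <= 2000:
        return "deep_1000_2000"
    return "gt_2000"


def stratum_proportions(entries: pd.DataFrame) -> pd.DataFrame:
    """Species counts and fractions per dive-depth stratum.

    ``entries`` needs a ``max_dive_depth_m`` column (NaN = unknown).
    Fractions are over species with known depth and sum to 1; the
    ``unknown`` row carries a NaN fraction.  All depths missing is an error.
    """
    strata = [depth_stratum(None if pd.isna(d) else float(d))
              for d in entries["max_dive_depth_m"]]
    counts = pd.Series(strata).value_counts()
    n_known = int(sum(counts.get(s, 0) for s in DEPTH_STRATA[:-1]))
    if n_known == 0:
        raise ValueError("all maximum dive depths are missing")
    rows = []
    for s in DEPTH_STRATA:
        c = int(counts.get(s, 0))
        frac = c / n_known if s != "unknown" else np.nan
        rows.append({"stratum": s, "count": c, "fraction": frac})
    return pd.DataFrame(rows)
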