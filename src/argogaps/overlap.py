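"""Spatial overlap indices between species ranges and observing-network
coldspots.

For a species range and the coldspot set within a region,

    OV_coldspot = S / C    (fraction of coldspot surface covered by the range)
    OV_range    = S / R    (fraction of the range lying in coldspots)

where S is the shared surface, C the coldspot surface and R the range
surface, all in km² (cell areas vary with latitude, so counts and areas
differ).  When C or R is zero the corresponding index is undefined (NaN),
never 0: the absence of a coldspot is not the absence of overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaps import ColdspotMap
from .grid import SECTOR_NAMES
from .species import RichnessLayer

REGIONS = ("Global",) + SECTOR_NAMES


@dataclass
class OverlapRecord:
    species_id: str
    region: str
    S_km2: float
    C_km2: float
    R_km2: float
    ov_coldspot: float  # NaN when C == 0
    ov_range: float     # NaN when R == 0


def overlap_indices(presence: np.ndarray, cmap: ColdspotMap | np.ndarray,
                    areas: np.ndarray, region_mask: np.ndarray | None = None,
                    species_id: str = "", region: str = "Global") -> OverlapRecord:
    """Compute S, C, R and both overlap indices for one species and region.

    ``region_mask`` clips both the coldspot surface C and the range surface
    R to the region (None means global).  Passing ``areas`` of all ones
    gives the cell-count debugging mode.
    """
    cold = cmap.mask if isinstance(cmap, ColdspotMap) else np.asarray(cmap, dtype=bool)
    presence = np.asarray(presence, dtype=bool)
    areas = np.asarray(areas, dtype=float)
    if presence.shape != cold.shape or presence.shape != areas.shape:
        raise ValueError("raster shapes do not match")
    if region_mask is None:
        region_mask = np.ones(presence.shape, dtype=bool)
    else:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != presence.shape:
            raise ValueError("region mask shape does not match")
        if not region_mask.any():
            raise ValueError("region mask is empty")
    S = float(areas[presence & cold & region_mask].sum())
    C = float(areas[cold & region_mask].sum())
    R = float(areas[presence & region_mask].sum())
    ov_c = S / C if C > 0 else np.nan
    ov_r = S / R if R > 0 else np.nan
    return OverlapRecord(species_id=species_id, region=region,
                         S_km2=S, C_km2=C, R_km2=R,
                         ov_coldspot=ov_c, ov_range=ov_r)


def overlap_table(presences: dict[str, np.ndarray], species_table: pd.DataFrame,
                  cmap: ColdspotMap, areas: np.ndarray, sector_id: np.ndarray,
                  low: float = 0.10, high: float = 0.50) -> tuple[pd.DataFrame, dict]:
    """Per-species x per-region overlap records plus distribution summaries.

    Regions are Global plus the five latitudinal sectors.  Summary counts
    use strict inequalities on the global records (< low, > high) and skip
    undefined (NaN) indices.  ``species_table`` needs ``species_id`` and
    ``taxon`` columns for the cross-taxon means.
    """
    if not presences:
        raise ValueError("no species presences given")
    taxon_of = dict(zip(species_table["species_id"], species_table["taxon"]))
    records = []
    for sid, pres in presences.items():
        for ridx, region in enumerate(REGIONS):
            rmask = None if region == "Global" else (sector_id == ridx - 1)
            if rmask is not None and not rmask.any():
                continue
            rec = overlap_indices(pres, cmap, areas, rmask,
                                  species_id=sid, region=region)
            records.append(rec)
    df = pd.DataFrame([r.__dict__ for r in records])
    df["taxon"] = df["species_id"].map(taxon_of)

    g = df[df["region"] == "Global"]
    summary = {
        "n_species": int(g["species_id"].nunique()),
        "n_ov_coldspot_below": int((g["ov_coldspot"] < low).sum()),
        "n_ov_coldspot_above": int((g["ov_coldspot"] > high).sum()),
        "n_ov_range_above": int((g["ov_range"] > high).sum()),
        "mean_ov_coldspot_by_region": (
            df.dropna(subset=["ov_coldspot"])
              .groupby("region", sort=False)["ov_coldspot"].mean().to_dict()),
        "mean_ov_coldspot_by_taxon_region": (
            df.dropna(subset=["ov_coldspot"])
              .groupby(["taxon", "region"], sort=False)["ov_coldspot"].mean()
              .reset_index()),
    }
    return df, summary


def overlap_species_map(richness: RichnessLayer, cmap: ColdspotMap) -> tuple[np.ndarray, np.ndarray]:
    """Three-class map of coldspots against a taxon's richness.

    Returns ``(classes, values)``: class 0 = non-coldspot, 1 = coldspot
    without any species of the taxon ("blue"), 2 = coldspot with species
    ("red"); ``values`` carries the taxon's normalized richness on class-2
    cells and NaN elsewhere.
    """
    cold = cmap.mask
    if richness.count.shape != cold.shape:
        raise ValueError("raster shapes do not match")
    classes = np.zeros(cold.shape, dtype=np.int8)
    has_sp = richness.count > 0
    classes[cold & ~has_sp] = 1
    classes[cold & has_sp] = 2
    values = np.where(classes == 2, richness.normalized, np.nan)
    return classes, values
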