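"""Stage runner: synth -> gaps -> coldspots -> species -> overlap ->
telemetry -> report, each reading and writing files under the configured
work directory and recording a manifest (config hash, input hashes,
package version).  Deterministic stages rerun byte-identically."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as agio
from .config import RunConfig
from .gaps import (bin_profiles, build_gap_stack, extract_coldspots,
                   coldspot_summary, GapStack, ColdspotMap)
from .grid import GlobalGrid, StaticMasks, cell_areas, make_grid
from .overlap import overlap_table, overlap_species_map
from .render import render_map
from .species import (TAXA, rasterize_eoo, range_area, taxon_richness,
                      composite, stratum_proportions)
from .synthetic import (Scenario, PlantedColdspot, gen_world, gen_profiles,
                        gen_species, gen_tracks, TELEMETRY_TAXA)
from .telemetry import grid_telemetry, tristate_overlap

log = logging.getLogger(__name__)

STAGES = ("synth", "gaps", "coldspots", "species", "overlap", "telemetry", "report")


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _manifest(cfg: RunConfig, stage: str, inputs: list[Path], outputs: list[Path]):
    wd = Path(cfg.workdir)
    man = {
        "stage": stage,
        "config_sha256": cfg.digest(),
        "version": __version__,
        "inputs": {p.name: _sha(p) for p in inputs if p.exists()},
        "outputs": [p.name for p in outputs],
    }
    (wd / f"manifest_{stage}.json").write_text(json.dumps(man, indent=2, sort_keys=True))
    return man


def _areas(cfg: RunConfig, grid: GlobalGrid) -> np.ndarray:
    if cfg.area_mode == "cells":
        return np.ones(grid.shape)
    return cell_areas(grid)


def _statics_path(cfg) -> Path:
    return Path(cfg.inputs.get("statics", Path(cfg.workdir) / "statics.nc"))


def _load_statics(cfg) -> tuple[StaticMasks, GlobalGrid]:
    layers, grid = agio.read_rasters(_statics_path(cfg))
    masks = StaticMasks(ocean=layers["ocean"].astype(bool),
                        depth_m=layers["depth_m"],
                        eez_id=layers["eez_id"],
                        sector_id=layers["sector_id"])
    return masks, grid


def _scenario(cfg: RunConfig) -> Scenario:
    ov = dict(cfg.scenario)
    planted = tuple(PlantedColdspot(**p) for p in ov.pop("planted_coldspots", ()))
    years = tuple(cfg.year_list)
    return Scenario(seed=cfg.seed, years=years, planted_coldspots=planted, **ov)


# ------------------------------------------------------------------ stages

def stage_synth(cfg: RunConfig) -> dict:
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    scn = _scenario(cfg)
    world = gen_world(scn)
    agio.write_rasters(wd / "statics.nc",
                       {"ocean": world.ocean,
                        "depth_m": np.where(np.isnan(world.depth_m), -1.0, world.depth_m),
                        "eez_id": world.eez_id,
                        "sector_id": world.sector_id.astype(np.int32)},
                       scn.grid)
    profiles = gen_profiles(scn, world)
    agio.write_argo_index(profiles, wd / "argo_index.csv")
    table, presences, caps = gen_species(scn, world)
    table = table.assign(eoo_path="species_presence.nc")
    table.to_csv(wd / "species.csv", index=False)
    stack = np.stack([presences[s] for s in table["species_id"]])
    agio.write_rasters(wd / "species_presence.nc", {"presence": stack}, scn.grid,
                       extra_dims={"species": np.arange(stack.shape[0])})
    geoms = {}
    for sid, (lon0, lat0, radius) in caps.items():
        try:
            geoms[sid] = agio.cap_polygon(lon0, lat0, radius)
        except ValueError:
            pass  # polar / hemispheric caps are carried by the raster only
    agio.write_eoo_geojson(geoms, wd / "eoo_caps.geojson")
    tracks = gen_tracks(scn, table, caps)
    tracks.to_csv(wd / "telemetry.csv", index=False)
    (wd / "scenario.json").write_text(json.dumps(scn.to_dict(), indent=2,
                                                 sort_keys=True, default=str))
    outs = [wd / n for n in ("statics.nc", "argo_index.csv", "species.csv",
                             "species_presence.nc", "eoo_caps.geojson",
                             "telemetry.csv", "scenario.json")]
    return _manifest(cfg, "synth", [], outs)


def stage_gaps(cfg: RunConfig) -> dict:
    wd = Path(cfg.workdir)
    masks, grid = _load_statics(cfg)
    index_path = Path(cfg.inputs.get("argo_index", wd / "argo_index.csv"))
    profiles = agio.read_argo_index(index_path)
    years = cfg.year_list
    densities = [bin_profiles(profiles, grid, y) for y in years]
    stack = build_gap_stack(densities, masks.ocean, q=cfg.q)
    agio.write_rasters(wd / "density.nc",
                       {"counts": np.stack([d.counts for d in densities])},
                       grid, extra_dims={"year": years})
    agio.write_rasters(wd / "gaps.nc", {"gap": stack.gap}, grid,
                       extra_dims={"year": years})
    agio.write_rasters(wd / "persistence.nc", {"persistence": stack.persistence}, grid)
    outs = [wd / "density.nc", wd / "gaps.nc", wd / "persistence.nc"]
    return _manifest(cfg, "gaps", [index_path, _statics_path(cfg)], outs)


def stage_coldspots(cfg: RunConfig) -> dict:
    wd = Path(cfg.workdir)
    masks, grid = _load_statics(cfg)
    layers, _ = agio.read_rasters(wd / "persistence.nc")
    areas = _areas(cfg, grid)
    cmap = extract_coldspots(layers["persistence"],
                             threshold=cfg.persistence_threshold,
                             min_cells=cfg.min_cells,
                             connectivity=cfg.connectivity,
                             wrap=cfg.wrap, areas=areas)
    agio.write_rasters(wd / "coldspots.nc", {"label": cmap.labels}, grid)
    cmap.table.to_csv(wd / "coldspot_components.csv", index=False)
    summ = coldspot_summary(cmap, masks, areas)
    summ["by_sector"].to_csv(wd / "coldspot_by_sector.csv", index=False)
    summ["by_depth_class"].to_csv(wd / "coldspot_by_depth.csv", index=False)
    summ["eez_ranking"].to_csv(wd / "coldspot_eez_ranking.csv", index=False)
    scalars = {k: v for k, v in summ.items() if not isinstance(v, pd.DataFrame)}
    (wd / "coldspot_summary.json").write_text(json.dumps(scalars, indent=2, sort_keys=True))
    if cfg.render:
        render_map(layers["persistence"], grid, wd / "persistence.png",
                   projection=cfg.projection, title="gap persistence")
        render_map(cmap.labels > 0, grid, wd / "coldspots.png",
                   projection=cfg.projection, cmap="Reds", title="coldspots")
    outs = [wd / n for n in ("coldspots.nc", "coldspot_components.csv",
                             "coldspot_summary.json")]
    return _manifest(cfg, "coldspots", [wd / "persistence.nc", _statics_path(cfg)], outs)


def _load_presences(cfg, masks, grid) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    wd = Path(cfg.workdir)
    table = agio.read_species_csv(Path(cfg.inputs.get("species_csv", wd / "species.csv")))
    presences: dict[str, np.ndarray] = {}
    raster_cache: dict[str, np.ndarray] = {}
    for i, row in table.iterrows():
        src = str(row.get("eoo_path", "") or "")
        path = wd / src if src and not Path(src).is_absolute() else Path(src)
        if src.endswith(".nc"):
            if src not in raster_cache:
                layers, _ = agio.read_rasters(path)
                raster_cache[src] = layers["presence"]
            presences[row["species_id"]] = raster_cache[src][i].astype(bool)
        elif src.endswith(".geojson") or src.endswith(".json"):
            geoms = agio.read_eoo_geojson(path)
            geom = geoms.get(row["species_id"])
            presences[row["species_id"]] = rasterize_eoo(
                geom, grid, ocean=masks.ocean, species=row["species_id"])
        else:
            raise ValueError(f"no EOO source for species {row['species_id']!r}")
    return table, presences


def stage_species(cfg: RunConfig) -> dict:
    wd = Path(cfg.workdir)
    masks, grid = _load_statics(cfg)
    areas = _areas(cfg, grid)
    table, presences = _load_presences(cfg, masks, grid)
    layers = {}
    out_rasters = {}
    for taxon in TAXA:
        ids = table.loc[table["taxon"] == taxon, "species_id"]
        if len(ids) == 0:
            continue
        rl = taxon_richness([presences[s] for s in ids], taxon)
        layers[taxon] = rl
        out_rasters[f"count_{taxon}"] = rl.count
        out_rasters[f"norm_{taxon}"] = rl.normalized
    if set(layers) == set(TAXA):
        out_rasters["composite"] = composite(layers, mode=cfg.composite_mode).value
    agio.write_rasters(wd / "richness.nc", out_rasters, grid)
    ra = pd.DataFrame({
        "species_id": table["species_id"],
        "taxon": table["taxon"],
        "range_area_km2": [range_area(presences[s], areas) for s in table["species_id"]],
    })
    ra.to_csv(wd / "range_areas.csv", index=False)
    stratum_proportions(table).to_csv(wd / "depth_strata.csv", index=False)
    outs = [wd / "richness.nc", wd / "range_areas.csv", wd / "depth_strata.csv"]
    return _manifest(cfg, "species", [wd / "species.csv", _statics_path(cfg)], outs)


def stage_overlap(cfg: RunConfig) -> dict:
    wd = Path(cfg.workdir)
    masks, grid = _load_statics(cfg)
    areas = _areas(cfg, grid)
    table, presences = _load_presences(cfg, masks, grid)
    labels, _ = agio.read_rasters(wd / "coldspots.nc")
    comp = pd.read_csv(wd / "coldspot_components.csv")
    cmap = ColdspotMap(labels=labels["label"], table=comp)
    records, summary = overlap_table(presences, table, cmap, areas, masks.sector_id)
    records.to_csv(wd / "overlap_records.csv", index=False)
    summary_out = dict(summary)
    summary_out["mean_ov_coldspot_by_taxon_region"] = \
        summary["mean_ov_coldspot_by_taxon_region"].to_dict(orient="records")
    (wd / "overlap_summary.json").write_text(json.dumps(summary_out, indent=2,
                                                        sort_keys=True))
    rich, _ = agio.read_rasters(wd / "richness.nc")
    maps = {}
    for taxon in TAXA:
        key = f"count_{taxon}"
        if key not in rich:
            continue
        from .species import RichnessLayer
        rl = RichnessLayer(taxon=taxon, count=rich[key], normalized=rich[f"norm_{taxon}"])
        classes, values = overlap_species_map(rl, cmap)
        maps[f"class_{taxon}"] = classes.astype(np.int32)
        maps[f"value_{taxon}"] = np.where(np.isnan(values), -1.0, values)
    agio.write_rasters(wd / "overlap_taxon_maps.nc", maps, grid)
    outs = [wd / "overlap_records.csv", wd / "overlap_summary.json",
            wd / "overlap_taxon_maps.nc"]
    return _manifest(cfg, "overlap",
                     [wd / "coldspots.nc", wd / "species.csv"], outs)


def stage_telemetry(cfg: RunConfig) -> dict:
    wd = Path(cfg.workdir)
    masks, grid = _load_statics(cfg)
    areas = _areas(cfg, grid)
    table, presences = _load_presences(cfg, masks, grid)
    labels, _ = agio.read_rasters(wd / "coldspots.nc")
    cmap = ColdspotMap(labels=labels["label"],
                       table=pd.read_csv(wd / "coldspot_components.csv"))
    tel_path = Path(cfg.inputs.get("telemetry_csv", wd / "telemetry.csv"))
    points = agio.read_telemetry_csv(tel_path)
    sp_taxon = dict(zip(table["species_id"], table["taxon"]))
    rasters, rows = {}, []
    for taxon in TELEMETRY_TAXA:
        ids = [s for s in table.loc[table["taxon"] == taxon, "species_id"]]
        pts = points[points["species_id"].map(sp_taxon) == taxon]
        tg = grid_telemetry(pts, grid)
        eoo = np.zeros(grid.shape, dtype=bool)
        for s in ids:
            eoo |= presences[s]
        classes, area_tab = tristate_overlap(tg, eoo, cmap, areas)
        rasters[f"telemetry_count_{taxon}"] = tg.count.astype(np.int32)
        rasters[f"tristate_{taxon}"] = classes.astype(np.int32)
        area_tab.insert(0, "taxon", taxon)
        rows.append(area_tab)
    agio.write_rasters(wd / "telemetry_grids.nc", rasters, grid)
    pd.concat(rows, ignore_index=True).to_csv(wd / "tristate_areas.csv", index=False)
    outs = [wd / "telemetry_grids.nc", wd / "tristate_areas.csv"]
    return _manifest(cfg, "telemetry", [tel_path, wd / "coldspots.nc"], outs)


def stage_report(cfg: RunConfig) -> dict:
    wd = Path(cfg.workdir)
    report: dict = {"config_sha256": cfg.digest(), "version": __version__}
    cj = wd / "coldspot_summary.json"
    if cj.exists():
        report["coldspots"] = json.loads(cj.read_text())
    comp = wd / "coldspot_components.csv"
    if comp.exists():
        t = pd.read_csv(comp)
        report["n_coldspots"] = int(len(t))
        if len(t) == 0:
            report.setdefault("coldspots", {})["total_area_km2"] = 0.0
    oj = wd / "overlap_summary.json"
    if oj.exists():
        report["overlap"] = json.loads(oj.read_text())
    ta = wd / "tristate_areas.csv"
    if ta.exists():
        report["telemetry"] = pd.read_csv(ta).to_dict(orient="records")
    ds = wd / "depth_strata.csv"
    if ds.exists():
        report["depth_strata"] = pd.read_csv(ds).to_dict(orient="records")
    (wd / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return _manifest(cfg, "report", [], [wd / "report.json"])


_STAGE_FN = {
    "synth": stage_synth,
    "gaps": stage_gaps,
    "coldspots": stage_coldspots,
    "species": stage_species,
    "overlap": stage_overlap,
    "telemetry": stage_telemetry,
    "report": stage_report,
}


def run_stage(name: str, cfg: RunConfig) -> dict:
    """Run one pipeline stage; returns its manifest."""
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    log.info("running stage %s in %s", name, cfg.workdir)
    return _STAGE_FN[name](cfg)


def run_all(cfg: RunConfig) -> dict[str, dict]:
    """Run every stage in order; returns the manifests."""
    return {name: run_stage(name, cfg) for name in STAGES}
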