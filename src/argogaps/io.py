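"""Readers and writers for the file dialects the pipeline consumes.

Tables are CSV (gzip accepted via pandas inference); rasters are NetCDF
written with xarray's scipy backend (netCDF3).  netCDF3 has no boolean or
64-bit integer types, so boolean layers are stored as int8 with a marker
attribute and integers are cast to int32; the round-trip is lossless under
that contract.  Polygon input is GeoJSON read with shapely.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
import xarray as xr
from shapely.geometry import shape as shapely_shape, mapping as shapely_mapping

from .grid import GlobalGrid

log = logging.getLogger(__name__)

ARGO_INDEX_COLUMNS = ["file", "date", "latitude", "longitude", "ocean",
                      "profiler_type", "institution", "date_update"]


# ---------------------------------------------------------------- tables

def read_argo_index(path) -> pd.DataFrame:
    """Read profile positions from either supported CSV dialect.

    The Argo global-index dialect (``file,date,latitude,longitude,...``,
    date as YYYYMMDDHHMISS, '#' comment lines, platform id embedded in the
    file path) and a minimal dialect (``platform_id,timestamp,lat,lon``,
    ISO-8601) are auto-detected from the header.  Returns the minimal
    schema; unparseable rows are dropped with a logged count.
    """
    head = pd.read_csv(path, comment="#", nrows=0)
    cols = [c.strip() for c in head.columns]
    if "file" in cols and "date" in cols:
        df = pd.read_csv(path, comment="#",
                         usecols=["file", "date", "latitude", "longitude"],
                         dtype={"file": str, "date": str})
        ts = pd.to_datetime(df["date"], format="%Y%m%d%H%M%S", errors="coerce")
        out = pd.DataFrame({
            "platform_id": df["file"].str.split("/").str[1],
            "timestamp": ts,
            "lat": pd.to_numeric(df["latitude"], errors="coerce"),
            "lon": pd.to_numeric(df["longitude"], errors="coerce"),
        })
    elif "platform_id" in cols and "timestamp" in cols:
        df = pd.read_csv(path, comment="#", dtype={"platform_id": str})
        out = pd.DataFrame({
            "platform_id": df["platform_id"],
            "timestamp": pd.to_datetime(df["timestamp"], errors="coerce"),
            "lat": pd.to_numeric(df["lat"], errors="coerce"),
            "lon": pd.to_numeric(df["lon"], errors="coerce"),
        })
    else:
        raise ValueError(f"unrecognized profile index dialect in {path}")
    bad = out["timestamp"].isna() | out["lat"].isna() | out["lon"].isna()
    if bad.any():
        log.warning("read_argo_index: dropped %d unparseable rows from %s",
                    int(bad.sum()), path)
    return out[~bad].reset_index(drop=True)


def write_argo_index(profiles: pd.DataFrame, path) -> None:
    """Write profiles in the Argo global-index dialect."""
    ts = pd.to_datetime(profiles["timestamp"])
    # YYYYMMDDHHMISS via numpy ISO strings (much faster than strftime here)
    iso = np.datetime_as_string(ts.to_numpy(dtype="datetime64[s]"), unit="s")
    date = pd.Series(iso).str.replace(r"[-T:]", "", regex=True)
    pid = profiles["platform_id"].astype(str)
    out = pd.DataFrame({
        "file": "syn/" + pid + "/profiles/R" + pid + "_001.nc",
        "date": date,
        "latitude": profiles["lat"].round(3),
        "longitude": profiles["lon"].round(3),
        "ocean": "A",
        "profiler_type": 846,
        "institution": "SY",
        "date_update": date,
    })
    with open(path, "w") as fh:
        fh.write("# Synthetic profile index\n")
        out.to_csv(fh, index=False)


def read_species_csv(path) -> pd.DataFrame:
    """Species attribute table: species_id, name, taxon, max_dive_depth_m
    (empty = missing), optional eoo_path."""
    df = pd.read_csv(path)
    df["max_dive_depth_m"] = pd.to_numeric(df["max_dive_depth_m"], errors="coerce")
    return df


def read_telemetry_csv(path) -> pd.DataFrame:
    """Telemetry points: species_id, animal_id, timestamp, lon, lat.
    Extra columns (e.g. an ARGOS location class) are ignored."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    keep = ["species_id", "animal_id", "timestamp", "lon", "lat"]
    bad = df["timestamp"].isna() | df["lon"].isna() | df["lat"].isna()
    if bad.any():
        log.warning("read_telemetry_csv: dropped %d unparseable rows", int(bad.sum()))
    return df.loc[~bad, keep].reset_index(drop=True)


# ---------------------------------------------------------------- rasters

def _encode(arr: np.ndarray) -> tuple[np.ndarray, dict]:
    if arr.dtype == bool:
        return arr.astype(np.int8), {"stored_bool": 1}
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int32), {}
    return np.asarray(arr, dtype=np.float64), {}


def write_rasters(path, layers: dict[str, np.ndarray], grid: GlobalGrid,
                  extra_dims: dict[str, np.ndarray] | None = None) -> None:
    """Write named rasters to one NetCDF file.

    2-D layers have dims (lat, lon); 3-D layers use one leading dimension
    from ``extra_dims`` (e.g. ``{"year": [...]}``), matched by length.
    """
    data = {}
    for name, arr in layers.items():
        arr = np.asarray(arr)
        enc, attrs = _encode(arr)
        if arr.ndim == 2:
            data[name] = xr.DataArray(enc, dims=("lat", "lon"), attrs=attrs)
        elif arr.ndim == 3 and extra_dims:
            dim = next(d for d, v in extra_dims.items() if len(v) == arr.shape[0])
            data[name] = xr.DataArray(enc, dims=(dim, "lat", "lon"), attrs=attrs)
        else:
            raise ValueError(f"cannot store raster {name!r} of ndim {arr.ndim}")
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    if extra_dims:
        coords.update({k: np.asarray(v) for k, v in extra_dims.items()})
    ds = xr.Dataset(data, coords=coords,
                    attrs={"radius_km": grid.radius_km})
    ds.to_netcdf(path, engine="scipy")


def read_rasters(path) -> tuple[dict[str, np.ndarray], GlobalGrid]:
    """Read all rasters from a NetCDF file written by :func:`write_rasters`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
        grid = GlobalGrid(n_lat=ds.sizes["lat"], n_lon=ds.sizes["lon"],
                          radius_km=float(ds.attrs.get("radius_km", 6371.0)))
        out = {}
        for name, da in ds.data_vars.items():
            arr = da.values
            if da.attrs.get("stored_bool"):
                arr = arr.astype(bool)
            out[name] = arr
    return out, grid


# ---------------------------------------------------------------- polygons

def read_eoo_geojson(path) -> dict[str, shapely.geometry.base.BaseGeometry]:
    """Read EOO polygons from a GeoJSON FeatureCollection.

    Features are grouped by a ``species_id`` (or ``species``/``name``/``id``)
    property; multiple features per species are unioned.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    grouped: dict[str, list] = {}
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        sid = (props.get("species_id") or props.get("species")
               or props.get("name") or props.get("id") or f"feature_{i}")
        grouped.setdefault(str(sid), []).append(shapely_shape(f["geometry"]))
    return {sid: shapely.union_all(geoms) if len(geoms) > 1 else geoms[0]
            for sid, geoms in grouped.items()}


def write_eoo_geojson(geoms: dict, path) -> None:
    """Write species geometries as a GeoJSON FeatureCollection."""
    feats = [{"type": "Feature",
              "properties": {"species_id": sid},
              "geometry": shapely_mapping(g)}
             for sid, g in geoms.items()]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def cap_polygon(lon0: float, lat0: float, radius_deg: float, n: int = 144):
    """Geodesic cap boundary as a (Multi)Polygon in lon/lat degrees.

    Built in a frame centred on ``lon0`` then shifted back and split at the
    antimeridian.  Caps containing a pole (|lat0| + radius close to 90) have
    no simple polygon boundary and raise ``ValueError``.
    """
    if abs(lat0) + radius_deg >= 89.0 or radius_deg >= 89.0:
        raise ValueError("cap too close to a pole for polygon output")
    la0 = np.deg2rad(lat0)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    d = np.deg2rad(radius_deg)
    la = np.arcsin(np.sin(la0) * np.cos(d) + np.cos(la0) * np.sin(d) * np.cos(th))
    dlon = np.arctan2(np.sin(th) * np.sin(d) * np.cos(la0),
                      np.cos(d) - np.sin(la0) * np.sin(la))
    ring = list(zip(np.rad2deg(dlon) + lon0, np.rad2deg(la)))
    poly = shapely.Polygon(ring)
    world = shapely.box(-180, -90, 180, 90)
    parts = [poly.intersection(world)]
    for off in (-360.0, 360.0):
        shifted = shapely.affinity.translate(poly, xoff=off)
        parts.append(shifted.intersection(world))
    out = shapely.union_all([p for p in parts if not p.is_empty])
    if out.is_empty:
        raise ValueError("cap polygon degenerate")
    return out
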