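"""Readers and writers for the pipeline's file formats.

Tabular inputs are plain CSV with fixed column schemas (validated on read);
gridded outputs go to NetCDF via xarray's scipy backend, and HPD regions to
GeoJSON polygons built from cell rectangles.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .grid import Grid
from .hmm import SmoothedTrack
from .preprocess import Deployment
from .ud import UD, HPDRegions

__all__ = [
    "SERIES_COLUMNS", "METADATA_COLUMNS", "EVENTS_COLUMNS", "POINTS_COLUMNS",
    "read_series_csv", "read_metadata_csv", "read_events_csv", "read_points_csv",
    "deployments_from_metadata", "select_tags",
    "smoothed_to_dataset", "write_smoothed_netcdf", "ud_to_dataset",
    "write_ud_netcdf", "hpd_regions_to_geojson", "config_hash",
]

SERIES_COLUMNS = ["tag_id", "timestamp", "depth_m", "temp_c"]
METADATA_COLUMNS = [
    "tag_id", "release_date", "release_lon", "release_lat",
    "popup_date", "popup_lon", "popup_lat", "ljfl_cm", "agency",
]
EVENTS_COLUMNS = ["tag_id", "date", "sunrise_ut", "sunset_ut"]
POINTS_COLUMNS = ["lon", "lat", "date", "event_type"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}; expected {cols}")


def read_series_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SERIES_COLUMNS, f"series CSV {path}")
    return df


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, METADATA_COLUMNS, f"metadata CSV {path}")
    return df


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EVENTS_COLUMNS, f"events CSV {path}")
    return df


def read_points_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, POINTS_COLUMNS[:3], f"points CSV {path}")
    return df


def deployments_from_metadata(meta: pd.DataFrame) -> list[Deployment]:
    deps = []
    for _, row in meta.iterrows():
        deps.append(
            Deployment(
                tag_id=str(row["tag_id"]),
                release_date=pd.Timestamp(row["release_date"]).date(),
                release_lon=float(row["release_lon"]),
                release_lat=float(row["release_lat"]),
                popup_date=pd.Timestamp(row["popup_date"]).date(),
                popup_lon=float(row["popup_lon"]),
                popup_lat=float(row["popup_lat"]),
                ljfl_cm=float(row["ljfl_cm"]),
                agency=str(row.get("agency", "")),
            )
        )
    return deps


def select_tags(
    deployments: Iterable[Deployment], min_days: int = 30
) -> tuple[list[Deployment], pd.DataFrame]:
    """Keep deployments of at least ``min_days`` days; report exclusions."""
    kept, rows = [], []
    for dep in deployments:
        ok = dep.duration_days >= min_days
        rows.append({"tag_id": dep.tag_id, "duration_days": dep.duration_days,
                     "selected": ok})
        if ok:
            kept.append(dep)
    return kept, pd.DataFrame(rows)


def _grid_coords(grid: Grid) -> dict:
    return {"lat": grid.lat, "lon": grid.lon}


def smoothed_to_dataset(track: SmoothedTrack, attrs: dict | None = None) -> xr.Dataset:
    """Per-day smoothed posteriors as a (time, lat, lon) dataset."""
    data = np.stack(track.fields)
    times = pd.to_datetime([d.isoformat() for d in track.dates])
    ds = xr.Dataset(
        {"probability": (("time", "lat", "lon"), data)},
        coords={"time": times, **_grid_coords(track.grid)},
        attrs=attrs or {},
    )
    return ds


def write_smoothed_netcdf(track: SmoothedTrack, path, attrs: dict | None = None) -> None:
    smoothed_to_dataset(track, attrs).to_netcdf(path, engine="scipy")


def ud_to_dataset(ud: UD, attrs: dict | None = None) -> xr.Dataset:
    base = {
        "stratum_quarter": ud.stratum.quarter,
        "stratum_maturity": ud.stratum.maturity,
        "n_fish_days": ud.n_fish_days,
    }
    base.update(attrs or {})
    return xr.Dataset(
        {"ud": (("lat", "lon"), ud.values)},
        coords=_grid_coords(ud.grid),
        attrs=base,
    )


def write_ud_netcdf(ud: UD, path, attrs: dict | None = None) -> None:
    ud_to_dataset(ud, attrs).to_netcdf(path, engine="scipy")


def hpd_regions_to_geojson(regions: HPDRegions, properties: dict | None = None) -> dict:
    """HPD masks as a GeoJSON FeatureCollection of (multi)polygons."""
    grid = regions.grid
    half_lon = grid.dlon / 2.0
    half_lat = grid.dlat / 2.0
    features = []
    for lv in regions.levels:
        mask = regions.mask(lv)
        iy, ix = np.nonzero(mask)
        cells = [
            box(grid.lon[j] - half_lon, grid.lat[i] - half_lat,
                grid.lon[j] + half_lon, grid.lat[i] + half_lat)
            for i, j in zip(iy, ix)
        ]
        geom = unary_union(cells) if cells else None
        props = {"level": lv, "n_cells": int(mask.sum()),
                 "area_km2": regions.area_km2(lv)}
        props.update(properties or {})
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(geom) if geom is not None else None,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def config_hash(cfg_dict: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance attrs."""

    def _default(o):
        if isinstance(o, (dt.date, dt.datetime)):
            return o.isoformat()
        return str(o)

    payload = json.dumps(cfg_dict, sort_keys=True, default=_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
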