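"""Readers and writers for the pipeline's external formats.

Seascapes travel as GeoJSON FeatureCollections (polygon features with id,
region, band and no_take properties), gridded fields as NetCDF via
xarray's scipy backend, tabular intermediates (arrest records, edge
lists, criteria) as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from reefsources.dispersal import ArrestTable
from reefsources.synth.seascape import Reef, Seascape

__all__ = [
    "seascape_to_geojson",
    "seascape_from_geojson",
    "write_seascape",
    "read_seascape",
    "write_field",
    "read_field",
    "write_arrests",
    "read_arrests",
]


def seascape_to_geojson(seascape: Seascape) -> dict:
    features = []
    for r in seascape.reefs:
        features.append({
            "type": "Feature",
            "geometry": mapping(r.polygon),
            "properties": {"id": r.id, "region": r.region, "band": r.band,
                           "no_take": r.no_take,
                           "area_km2": round(r.area, 6)},
        })
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"domain": list(seascape.domain),
                       "grid_spacing_km": seascape.grid_spacing},
    }


def seascape_from_geojson(doc: dict) -> Seascape:
    reefs = [
        Reef(id=str(f["properties"]["id"]),
             polygon=shape(f["geometry"]),
             region=int(f["properties"]["region"]),
             band=str(f["properties"].get("band", "")),
             no_take=bool(f["properties"].get("no_take", False)))
        for f in doc["features"]
    ]
    props = doc.get("properties", {})
    return Seascape(reefs=reefs,
                    domain=tuple(props["domain"]),
                    grid_spacing=float(props["grid_spacing_km"]))


def write_seascape(seascape: Seascape, path: str | Path) -> None:
    Path(path).write_text(json.dumps(seascape_to_geojson(seascape)))


def read_seascape(path: str | Path) -> Seascape:
    return seascape_from_geojson(json.loads(Path(path).read_text()))


def write_field(ds: xr.Dataset, path: str | Path) -> None:
    # scipy backend -> NetCDF3; object coords must be stringified first
    enc = ds.copy()
    for name in enc.variables:
        if enc[name].dtype == object:
            enc[name] = enc[name].astype(str)
    enc.to_netcdf(path, engine="scipy")


def read_field(path: str | Path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def write_arrests(table: ArrestTable, path: str | Path) -> None:
    df = table.records.copy()
    df.insert(0, "event_id", table.event_id)
    df["release_time_hours"] = table.release_time_hours
    df["released"] = df["source_id"].map(table.released)
    df.to_csv(path, index=False)


def read_arrests(path: str | Path) -> ArrestTable:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"sink_id": str, "source_id": str})
    df["arrest_age_days"] = pd.to_numeric(df["arrest_age_days"], errors="coerce")
    released = (df.drop_duplicates("source_id")
                  .set_index("source_id")["released"].astype(int).to_dict())
    event_id = str(df["event_id"].iloc[0])
    t0 = float(df["release_time_hours"].iloc[0])
    records = df[["source_id", "particle_id", "fate", "sink_id",
                  "arrest_age_days"]].copy()
    return ArrestTable(event_id=event_id, release_time_hours=t0,
                       records=records, released=released)
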