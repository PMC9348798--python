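"""Minimal GeoJSON read/write for shapely geometries (WGS84)."""

from __future__ import annotations

import json
from pathlib import Path

import shapely
from shapely.geometry import mapping, shape


def write_geojson(path: str | Path, geometries, properties=None) -> None:
    """Write geometries as a GeoJSON FeatureCollection."""
    geometries = list(geometries)
    properties = properties or [{} for _ in geometries]
    fc = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "geometry": mapping(g),
                        "properties": p}
                       for g, p in zip(geometries, properties)]}
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[shapely.Geometry]:
    """Read all feature geometries from a GeoJSON file."""
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    return [shape(f["geometry"] if "geometry" in f else f) for f in feats]
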