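"""Planar coordinate handling and GeoJSON input/output.

All internal geometry lives in a single local projected frame in metres.
Longitude/latitude appear only at the GPX / GeoJSON boundary, converted
through an equirectangular local tangent-plane projection anchored at a
reference point. For city-scale extents (a few km) the distortion of this
projection is far below GPS positional noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular projection centred on (``lat0``, ``lon0``).

    ``x`` grows east, ``y`` grows north, both in metres, origin at the
    anchor point.
    """

    lat0: float = 51.54
    lon0: float = -0.01

    def to_xy(self, lat: float, lon: float) -> tuple[float, float]:
        k = math.cos(math.radians(self.lat0))
        x = math.radians(lon - self.lon0) * EARTH_RADIUS_M * k
        y = math.radians(lat - self.lat0) * EARTH_RADIUS_M
        return x, y

    def to_latlon(self, x: float, y: float) -> tuple[float, float]:
        k = math.cos(math.radians(self.lat0))
        lon = self.lon0 + math.degrees(x / (EARTH_RADIUS_M * k))
        lat = self.lat0 + math.degrees(y / EARTH_RADIUS_M)
        return lat, lon


def write_geojson(path: str | Path, frame: pd.DataFrame, geometry_col: str = "geometry") -> None:
    """Write a DataFrame with a shapely geometry column as a GeoJSON FeatureCollection."""
    features = []
    props_cols = [c for c in frame.columns if c != geometry_col]
    for _, row in frame.iterrows():
        props = {}
        for c in props_cols:
            v = row[c]
            if hasattr(v, "item"):
                v = v.item()
            props[c] = v
        features.append(
            {"type": "Feature", "geometry": mapping(row[geometry_col]), "properties": props}
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_geojson(path: str | Path, geometry_col: str = "geometry") -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection into a DataFrame with shapely geometries."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection")
    rows: list[dict] = []
    geoms: list[BaseGeometry] = []
    for feat in payload["features"]:
        rows.append(feat.get("properties") or {})
        geoms.append(shape(feat["geometry"]))
    frame = pd.DataFrame(rows)
    frame[geometry_col] = geoms
    return frame


def planar_distance(x0: float, y0: float, x1: float, y1: float) -> float:
    return math.hypot(x1 - x0, y1 - y0)


def haversine_m(lat0: float, lon0: float, lat1: float, lon1: float) -> float:
    """Great-circle distance in metres; used only when inputs stay unprojected."""
    p0, p1 = math.radians(lat0), math.radians(lat1)
    dphi = p1 - p0
    dlmb = math.radians(lon1 - lon0)
    a = math.sin(dphi / 2) ** 2 + math.cos(p0) * math.cos(p1) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def hash_layers(frames: Iterable[pd.DataFrame]) -> str:
    """Stable content hash over geometry WKB and attributes, for determinism checks."""
    import hashlib

    h = hashlib.sha256()
    for frame in frames:
        for col in sorted(frame.columns):
            if col == "geometry":
                for g in frame[col]:
                    h.update(g.wkb)
            else:
                h.update(pd.util.hash_pandas_object(frame[col], index=False).values.tobytes())
    return h.hexdigest()
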