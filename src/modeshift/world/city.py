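"""Synthetic vector city: streets, parcels, parks, stations, PTAL points.

The city is a rectangular street grid in a local metric frame. One corner
district is designated as the redevelopment ("intervention") district: its
parcels are denser and more mixed-use, it contains a park, and public
transport scores are boosted there. All layers are plain DataFrames with a
shapely ``geometry`` column so they round-trip through GeoJSON without a
GIS dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box

from modeshift.geo import read_geojson, write_geojson

LAND_USES = ("residential", "commercial", "office", "entertainment", "institutional")
PARK_CLASSES = ("Metropolitan", "District", "Local")


@dataclass
class CityLayers:
    """All vector layers of one synthetic city, in metres, one planar frame."""

    streets: pd.DataFrame  # geometry: LineString, length_m
    parcels: pd.DataFrame  # geometry: Polygon, land_use, floor_area_m2, residential_units
    parks: pd.DataFrame  # park_id, geometry: Polygon, park_class
    park_entrances: pd.DataFrame  # park_id, geometry: Point (on the street network)
    underground_stations: pd.DataFrame  # station_id, geometry: Point
    overground_stations: pd.DataFrame  # station_id, geometry: Point
    rail_lines: pd.DataFrame  # geometry: LineString
    ptal_points: pd.DataFrame  # point_id, geometry: Point, score in [0, 8]
    target_district: Polygon  # the redeveloped district movers relocate into

    _LAYER_NAMES = (
        "streets",
        "parcels",
        "parks",
        "park_entrances",
        "underground_stations",
        "overground_stations",
        "rail_lines",
        "ptal_points",
    )

    def layer_frames(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in self._LAYER_NAMES}

    def write(self, out_dir: str | Path) -> None:
        """One GeoJSON file per layer, plus the district polygon."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.layer_frames().items():
            write_geojson(out / f"{name}.geojson", frame)
        district = pd.DataFrame({"name": ["target_district"], "geometry": [self.target_district]})
        write_geojson(out / "target_district.geojson", district)

    @classmethod
    def read(cls, in_dir: str | Path) -> "CityLayers":
        src = Path(in_dir)
        frames = {name: read_geojson(src / f"{name}.geojson") for name in cls._LAYER_NAMES}
        district = read_geojson(src / "target_district.geojson")["geometry"].iloc[0]
        return cls(target_district=district, **frames)


def _grid_streets(extent_m: float, block_m: float) -> pd.DataFrame:
    """Full rectangular grid of street segments, one row per block edge."""
    n = int(round(extent_m / block_m))
    xs = np.arange(n + 1) * block_m
    segs: list[LineString] = []
    for x in xs:
        for j in range(n):
            segs.append(LineString([(x, j * block_m), (x, (j + 1) * block_m)]))
    for y in xs:
        for i in range(n):
            segs.append(LineString([(i * block_m, y), ((i + 1) * block_m, y)]))
    return pd.DataFrame({"geometry": segs, "length_m": [s.length for s in segs]})


def generate_city(
    seed: int,
    extent_m: float = 4000.0,
    *,
    block_m: float = 200.0,
    n_parks: int = 3,
    n_underground: int = 6,
    n_overground: int = 3,
    district_frac: float = 0.3,
    ptal_spacing_m: float = 500.0,
) -> CityLayers:
    """Build a deterministic grid city.

    Parameters
    ----------
    seed
        Drives every random choice; identical seeds give identical layers.
    extent_m
        Side of the square city. Must be at least 2 km so that 1-km
        network buffers fit inside.
    """
    if extent_m < 2000:
        raise ValueError(f"extent_m must be >= 2000 so 1-km buffers fit (got {extent_m})")
    rng = np.random.default_rng(seed)
    n = int(round(extent_m / block_m))
    streets = _grid_streets(extent_m, block_m)

    # Redevelopment district: square in the north-east corner.
    dside = max(block_m, round(extent_m * district_frac / block_m) * block_m)
    district = box(extent_m - dside, extent_m - dside, extent_m, extent_m)

    # Parks claim whole blocks; one is placed inside the district so movers
    # end up closer to green space by construction.
    park_rows, entrance_rows = [], []
    park_blocks: set[tuple[int, int]] = set()
    if n_parks > 0:
        di0 = n - int(dside / block_m)  # first block index inside the district
        candidates_in = [(i, j) for i in range(di0, n) for j in range(di0, n)]
        candidates_out = [(i, j) for i in range(n) for j in range(n) if i < di0 or j < di0]
        chosen = [candidates_in[rng.integers(len(candidates_in))]]
        k = min(n_parks - 1, len(candidates_out))
        idx = rng.choice(len(candidates_out), size=k, replace=False)
        chosen += [candidates_out[i] for i in idx]
        for pid, (i, j) in enumerate(chosen):
            park_blocks.add((i, j))
            x0, y0 = i * block_m, j * block_m
            poly = box(x0 + 10, y0 + 10, x0 + block_m - 10, y0 + block_m - 10)
            klass = PARK_CLASSES[int(rng.integers(len(PARK_CLASSES)))]
            park_rows.append({"park_id": pid, "geometry": poly, "park_class": klass})
            # Two entrances on opposite block edges; both lie on street lines.
            entrance_rows.append({"park_id": pid, "geometry": Point(x0 + block_m / 2, y0)})
            entrance_rows.append({"park_id": pid, "geometry": Point(x0 + block_m / 2, y0 + block_m)})
    else:
        warnings.warn("city generated with no parks; park-distance exposures will be missing")
    parks = pd.DataFrame(park_rows, columns=["park_id", "geometry", "park_class"])
    entrances = pd.DataFrame(entrance_rows, columns=["park_id", "geometry"])

    # Parcels: one per non-park block, inset from the streets.
    parcel_rows = []
    use_probs_out = np.array([0.55, 0.15, 0.12, 0.08, 0.10])
    use_probs_in = np.array([0.45, 0.20, 0.12, 0.13, 0.10])  # more mixed in the district
    for i in range(n):
        for j in range(n):
            if (i, j) in park_blocks:
                continue
            x0, y0 = i * block_m, j * block_m
            poly = box(x0 + 15, y0 + 15, x0 + block_m - 15, y0 + block_m - 15)
            inside = district.contains(poly.centroid)
            probs = use_probs_in if inside else use_probs_out
            use = LAND_USES[int(rng.choice(len(LAND_USES), p=probs))]
            storeys = int(rng.integers(6, 12)) if inside else int(rng.integers(1, 4))
            floor_area = poly.area * storeys * float(rng.uniform(0.3, 0.6))
            units = 0
            if use == "residential":
                per_storey = rng.poisson(30 if inside else 8)
                units = int(max(1, per_storey * storeys))
            parcel_rows.append(
                {
                    "geometry": poly,
                    "land_use": use,
                    "floor_area_m2": float(floor_area),
                    "residential_units": units,
                }
            )
    parcels = pd.DataFrame(parcel_rows)

    # Rail: one horizontal line through the city with overground stations on it.
    rail_y = round(0.6 * n) * block_m
    rail = pd.DataFrame({"geometry": [LineString([(0, rail_y), (extent_m, rail_y)])]})
    over_x = np.linspace(0.15, 0.95, max(n_overground, 1)) * extent_m
    over = pd.DataFrame(
        {
            "station_id": np.arange(len(over_x)),
            "geometry": [Point(round(x / block_m) * block_m, rail_y) for x in over_x],
        }
    )

    # Underground stations at street nodes, weighted toward the district.
    node_xy = [(i * block_m, j * block_m) for i in range(n + 1) for j in range(n + 1)]
    node_xy = np.array(node_xy, dtype=float)
    in_district = np.array([district.buffer(1).contains(Point(x, y)) for x, y in node_xy])
    w = np.where(in_district, 4.0, 1.0)
    w /= w.sum()
    n_under = min(n_underground, len(node_xy))
    idx = rng.choice(len(node_xy), size=n_under, replace=False, p=w)
    under = pd.DataFrame(
        {
            "station_id": np.arange(n_under),
            "geometry": [Point(*node_xy[i]) for i in sorted(idx)],
        }
    )

    # PTAL sample points on a coarse grid; score decays with distance to the
    # nearest station and is boosted inside the district (0-8 scale).
    pts = []
    station_xy = np.array(
        [[p.x, p.y] for p in pd.concat([under["geometry"], over["geometry"]])], dtype=float
    )
    gx = np.arange(ptal_spacing_m / 2, extent_m, ptal_spacing_m)
    pid = 0
    for x in gx:
        for y in gx:
            d = np.sqrt(((station_xy - [x, y]) ** 2).sum(axis=1)).min() if len(station_xy) else 1e9
            score = 6.5 * np.exp(-d / 800.0) + (1.5 if district.contains(Point(x, y)) else 0.0)
            score += rng.normal(0, 0.15)
            pts.append({"point_id": pid, "geometry": Point(x, y), "score": float(np.clip(score, 0, 8))})
            pid += 1
    ptal = pd.DataFrame(pts)

    return CityLayers(
        streets=streets,
        parcels=parcels,
        parks=parks,
        park_entrances=entrances,
        underground_stations=under,
        overground_stations=over,
        rail_lines=rail,
        ptal_points=ptal,
        target_district=district,
    )
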