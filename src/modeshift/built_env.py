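"""Built-environment exposures per home address.

Walkability is the sum of three z-transformed components — land-use mix
(normalised entropy of floor-area shares over five use classes),
residential density (thousand residential units per km² of residential
land) and street connectivity (junctions of degree >= 3 per km of road) —
all measured inside a 1-km street-network buffer around the address.
z-transforms are referenced to the baseline cohort distribution and
frozen, so follow-up scores and change scores share one scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring, unary_union

from modeshift.network import attach_point, build_street_graph
from modeshift.world.city import LAND_USES, CityLayers

WALKABILITY_COMPONENTS = ("land_use_mix", "residential_density", "street_connectivity")


@dataclass
class NetworkBuffer:
    address: Point
    radius_m: float
    reachable_length_m: float
    edge_portions: list[LineString]
    polygon: Polygon
    node_distances: dict = field(repr=False, default_factory=dict)


def _oriented(geom: LineString, node_xy: tuple[float, float]) -> LineString:
    """Return geom starting at node_xy (flip if stored the other way)."""
    x0, y0 = geom.coords[0][:2]
    if math.hypot(x0 - node_xy[0], y0 - node_xy[1]) < 1e-6:
        return geom
    return LineString(geom.coords[::-1])


def network_buffer(
    address: Point,
    g: nx.Graph,
    radius_m: float = 1000.0,
    *,
    snap_tolerance_m: float = 100.0,
    dilate_m: float = 25.0,
) -> NetworkBuffer:
    """Shortest-path reachable subnetwork; partial edges cut at exactly the radius."""
    work = g.copy()
    src = attach_point(work, address, label="__address__", tolerance_m=snap_tolerance_m)
    dist = nx.single_source_dijkstra_path_length(work, src, cutoff=radius_m, weight="length")

    portions: list[LineString] = []
    total = 0.0
    for u, v, data in work.edges(data=True):
        du = dist.get(u, math.inf)
        dv = dist.get(v, math.inf)
        if du > radius_m and dv > radius_m:
            continue
        length = data["length"]
        geom = data["geometry"]
        from_u = max(0.0, radius_m - du) if du <= radius_m else 0.0
        from_v = max(0.0, radius_m - dv) if dv <= radius_m else 0.0
        if from_u + from_v >= length:
            portions.append(geom)
            total += length
            continue
        ux, uy = work.nodes[u]["x"], work.nodes[u]["y"]
        vx, vy = work.nodes[v]["x"], work.nodes[v]["y"]
        if from_u > 0:
            gu = _oriented(geom, (ux, uy))
            portions.append(substring(gu, 0, from_u))
        if from_v > 0:
            gv = _oriented(geom, (vx, vy))
            portions.append(substring(gv, 0, from_v))
        total += min(length, from_u + from_v)

    poly = unary_union([p.buffer(dilate_m) for p in portions]) if portions else address.buffer(dilate_m)
    return NetworkBuffer(
        address=address,
        radius_m=radius_m,
        reachable_length_m=total,
        edge_portions=portions,
        polygon=poly,
        node_distances=dist,
    )


def land_use_mix(buffer: NetworkBuffer, parcels: pd.DataFrame) -> float:
    """Normalised entropy in [0, 1] of floor-area shares over the five use
    classes, among parcels intersecting the buffer polygon. NaN when no
    floor space falls inside."""
    mask = np.fromiter(
        (buffer.polygon.intersects(geom) for geom in parcels["geometry"]),
        dtype=bool,
        count=len(parcels),
    )
    inside = parcels.loc[mask]
    totals = inside.groupby("land_use")["floor_area_m2"].sum()
    grand = totals.sum()
    if grand <= 0:
        return float("nan")
    entropy = 0.0
    for use in LAND_USES:
        p = totals.get(use, 0.0) / grand
        if p > 0:
            entropy -= p * math.log(p)
    return entropy / math.log(len(LAND_USES))


def residential_density(buffer: NetworkBuffer, parcels: pd.DataFrame) -> float:
    """Thousand residential units per km² of residential land in the buffer."""
    res = parcels[parcels["land_use"] == "residential"]
    mask = np.fromiter(
        (buffer.polygon.intersects(geom) for geom in res["geometry"]), dtype=bool, count=len(res)
    )
    inside = res.loc[mask]
    area_km2 = sum(geom.area for geom in inside["geometry"]) / 1e6
    if area_km2 <= 0:
        return float("nan")
    units = inside["residential_units"].sum()
    return float(units / area_km2 / 1000.0)


def street_connectivity(buffer: NetworkBuffer, g: nx.Graph) -> float:
    """Degree->=3 junctions inside the buffer per km of reachable road."""
    road_km = buffer.reachable_length_m / 1000.0
    if road_km <= 0:
        return float("nan")
    n_junctions = sum(
        1
        for node, deg in g.degree()
        if deg >= 3 and buffer.polygon.contains(Point(g.nodes[node]["x"], g.nodes[node]["y"]))
    )
    return n_junctions / road_km


def walkability_zsum(
    components: pd.DataFrame, reference: dict[str, tuple[float, float]] | None = None
) -> tuple[pd.Series, dict[str, tuple[float, float]]]:
    """Sum of z-scores of the three components.

    ``reference`` holds frozen (mean, sd) per component; when None it is
    computed from ``components`` (the baseline cohort) and returned for
    reuse at follow-up.
    """
    missing = [c for c in WALKABILITY_COMPONENTS if c not in components]
    if missing:
        raise ValueError(f"missing walkability components: {missing}")
    if reference is None:
        reference = {}
        for c in WALKABILITY_COMPONENTS:
            mu = float(components[c].mean())
            sd = float(components[c].std(ddof=1))
            if not sd > 0:
                raise ValueError(f"component {c!r} has zero variance in the reference cohort")
            reference[c] = (mu, sd)
    z = sum((components[c] - reference[c][0]) / reference[c][1] for c in WALKABILITY_COMPONENTS)
    return z, reference


def park_distance(
    address: Point,
    g: nx.Graph,
    park_entrances: pd.DataFrame,
    *,
    snap_tolerance_m: float = 100.0,
) -> float:
    """Shortest network distance (m) to the nearest entrance of any park."""
    if park_entrances is None or len(park_entrances) == 0:
        return float("nan")
    work = g.copy()
    src = attach_point(work, address, label="__address__", tolerance_m=snap_tolerance_m)
    targets = []
    for i, ent in enumerate(park_entrances["geometry"]):
        targets.append(attach_point(work, ent, label=("__entrance__", i), tolerance_m=snap_tolerance_m))
    dist = nx.single_source_dijkstra_path_length(work, src, weight="length")
    # straight-line offsets from the address / entrance to their snap points
    # count toward the distance
    src_off = work.nodes[src]["snap_offset"]
    best = min(
        (dist[t] + work.nodes[t]["snap_offset"] for t in targets if t in dist),
        default=float("nan"),
    )
    return float(best + src_off) if np.isfinite(best) else float("nan")


def assign_ptal(address: Point, ptal_points: pd.DataFrame) -> float:
    """Score of the Euclidean-nearest PTAL sample point; ties -> lowest id."""
    if ptal_points is None or len(ptal_points) == 0:
        return float("nan")
    pts = ptal_points.sort_values("point_id")
    d = np.array([address.distance(geom) for geom in pts["geometry"]])
    return float(pts["score"].to_numpy()[int(np.argmin(d))])


class ExposureEngine:
    """Computes all exposures for many addresses over one city, reusing the
    street graph across calls."""

    def __init__(self, city: CityLayers, *, radius_m: float = 1000.0, dilate_m: float = 25.0):
        self.city = city
        self.radius_m = radius_m
        self.dilate_m = dilate_m
        self.graph = build_street_graph(city.streets)

    def exposure_row(self, address: Point) -> dict[str, float]:
        buf = network_buffer(address, self.graph, self.radius_m, dilate_m=self.dilate_m)
        return {
            "land_use_mix": land_use_mix(buf, self.city.parcels),
            "residential_density": residential_density(buf, self.city.parcels),
            "street_connectivity": street_connectivity(buf, self.graph),
            "park_distance_m": park_distance(address, self.graph, self.city.park_entrances),
            "ptal": assign_ptal(address, self.city.ptal_points),
        }

    def cohort_exposures(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """One row per participant-wave with walkability z-summed against the
        baseline cohort and frozen for follow-up."""
        rows = []
        cache: dict[tuple[float, float], dict[str, float]] = {}
        for wave in ("baseline", "followup"):
            for _, person in cohort.iterrows():
                key = (person[f"home_x_{wave}"], person[f"home_y_{wave}"])
                if key not in cache:
                    cache[key] = self.exposure_row(Point(*key))
                rows.append(
                    {"participant_id": person["participant_id"], "wave": wave, **cache[key]}
                )
        out = pd.DataFrame(rows)
        base = out[out["wave"] == "baseline"]
        _, ref = walkability_zsum(base[list(WALKABILITY_COMPONENTS)])
        out["walkability"], _ = walkability_zsum(out[list(WALKABILITY_COMPONENTS)], ref)
        return out
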