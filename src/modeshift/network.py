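"""Street-network graph utilities shared by routing and exposure modules.

Streets are undirected; nodes are segment endpoints keyed by rounded
coordinates (the generator emits exact grid coordinates, real data are
snapped to centimetres). Edge weights are metric lengths.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

_ROUND = 2  # centimetre key resolution


def _key(x: float, y: float) -> tuple[float, float]:
    return (round(x, _ROUND), round(y, _ROUND))


def build_street_graph(streets: pd.DataFrame) -> nx.Graph:
    """Undirected graph; every edge stores its geometry and length."""
    g = nx.Graph()
    for _, row in streets.iterrows():
        geom: LineString = row["geometry"]
        coords = list(geom.coords)
        u, v = _key(*coords[0][:2]), _key(*coords[-1][:2])
        g.add_node(u, x=u[0], y=u[1])
        g.add_node(v, x=v[0], y=v[1])
        # parallel duplicates: keep the shorter
        if g.has_edge(u, v) and g[u][v]["length"] <= geom.length:
            continue
        g.add_edge(u, v, length=float(geom.length), geometry=geom)
    return g


def nearest_node(g: nx.Graph, point: Point) -> tuple[float, float]:
    xs = np.array([d["x"] for _, d in g.nodes(data=True)])
    ys = np.array([d["y"] for _, d in g.nodes(data=True)])
    nodes = list(g.nodes)
    i = int(np.argmin((xs - point.x) ** 2 + (ys - point.y) ** 2))
    return nodes[i]


def nearest_edge(g: nx.Graph, point: Point) -> tuple[tuple, tuple, float]:
    """Edge (u, v) minimising point-to-geometry distance, plus that distance."""
    best, best_d = None, math.inf
    for u, v, data in g.edges(data=True):
        d = data["geometry"].distance(point)
        if d < best_d:
            best, best_d = (u, v), d
    if best is None:
        raise ValueError("graph has no edges")
    return best[0], best[1], best_d


def attach_point(g: nx.Graph, point: Point, label, tolerance_m: float = 100.0) -> object:
    """Snap ``point`` onto its nearest edge as a temporary node.

    Splits the host edge at the snapped position. Returns the new node id.
    Mutates ``g``; callers wanting a pristine graph should copy first.
    """
    u, v, d = nearest_edge(g, point)
    if d > tolerance_m:
        raise ValueError(
            f"point ({point.x:.0f}, {point.y:.0f}) is {d:.0f} m from the nearest street "
            f"(tolerance {tolerance_m:.0f} m)"
        )
    geom: LineString = g[u][v]["geometry"]
    pos = geom.project(point)
    snapped = geom.interpolate(pos)
    node = label
    g.add_node(node, x=snapped.x, y=snapped.y, snap_offset=float(point.distance(snapped)))
    # orient the projected position relative to u by comparing coordinates
    # (node ids may be labels, not coordinate keys, after earlier splits)
    fx, fy = geom.coords[0][:2]
    starts_at_u = math.hypot(fx - g.nodes[u]["x"], fy - g.nodes[u]["y"]) < 1e-6
    du = pos if starts_at_u else geom.length - pos
    g.remove_edge(u, v)  # replaced by the two halves below
    g.add_edge(node, u, length=float(du), geometry=LineString([(snapped.x, snapped.y), (g.nodes[u]["x"], g.nodes[u]["y"])]))
    g.add_edge(node, v, length=float(geom.length - du), geometry=LineString([(snapped.x, snapped.y), (g.nodes[v]["x"], g.nodes[v]["y"])]))
    return node


def shortest_path_coords(g: nx.Graph, src, dst) -> list[tuple[float, float]]:
    nodes = nx.shortest_path(g, src, dst, weight="length")
    return [(g.nodes[n]["x"], g.nodes[n]["y"]) for n in nodes]


def network_distance(g: nx.Graph, src, dst) -> float:
    return nx.shortest_path_length(g, src, dst, weight="length")
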