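"""Epoch-fidelity travel diaries: contiguous true-mode episodes per day.

Each participant-wave-day is tiled completely with episodes. Travel
episodes follow shortest paths on the street network (rail travel follows
the rail line); underground episodes start and end exactly at underground
station points and are flanked by short outdoor-stationary dwells at those
stations so the surrounding GPS record brackets the signal gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from modeshift.config import SimConfig
from modeshift.network import build_street_graph, nearest_node, shortest_path_coords
from modeshift.world.city import CityLayers
from modeshift.world.daylevel import BASELINE_START, FOLLOWUP_START

TRAVEL_MODES = ("walking", "cycling", "vehicle", "overground", "underground")
STATION_DWELL_S = 300  # outdoor dwell flanking an underground leg


@dataclass
class DiaryEpisode:
    participant_id: str
    wave: str
    day: int
    start: pd.Timestamp
    end: pd.Timestamp
    true_mode: str  # travel mode, stationary_in, or stationary_out
    path: LineString | Point  # traversed geometry (Point when stationary)
    speed_ms: float = 0.0

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def _traversal(coords: list[tuple[float, float]], needed_m: float) -> LineString:
    """Walk the polyline, ping-ponging, until ``needed_m`` metres are covered."""
    if len(coords) < 2:
        raise ValueError("need at least two coordinates to traverse")
    out = [coords[0]]
    covered = 0.0
    forward = True
    while covered < needed_m - 1e-9:
        seq = coords if forward else coords[::-1]
        for a, b in zip(seq[:-1], seq[1:]):
            seg = float(np.hypot(b[0] - a[0], b[1] - a[1]))
            if seg == 0:
                continue
            if covered + seg >= needed_m:
                f = (needed_m - covered) / seg
                out.append((a[0] + f * (b[0] - a[0]), a[1] + f * (b[1] - a[1])))
                covered = needed_m
                break
            out.append(b)
            covered += seg
        forward = not forward
    return LineString(out)


def _round10(seconds: float) -> int:
    return max(10, int(round(seconds / 10.0)) * 10)


def generate_diaries(
    cohort: pd.DataFrame, city: CityLayers, config: SimConfig, *, rng: np.random.Generator | None = None
) -> list[DiaryEpisode]:
    if config.fidelity != "epoch":
        raise ValueError("generate_diaries requires fidelity='epoch'")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    g = build_street_graph(city.streets)
    nodes = list(g.nodes)
    under_pts = list(city.underground_stations["geometry"])
    over_pts = list(city.overground_stations["geometry"])
    rail_coords = list(city.rail_lines["geometry"].iloc[0].coords) if len(city.rail_lines) else None

    episodes: list[DiaryEpisode] = []
    day_len_s = config.waking_hours * 3600
    for _, person in cohort.iterrows():
        offset = int(rng.integers(0, 7))
        for wave, wave_start in (("baseline", BASELINE_START), ("followup", FOLLOWUP_START)):
            home = Point(person[f"home_x_{wave}"], person[f"home_y_{wave}"])
            home_node = nearest_node(g, home)
            for day in range(1, config.wear_days + 1):
                date = wave_start + pd.Timedelta(days=offset + day - 1)
                t0 = date + pd.Timedelta(hours=config.day_start_hour)
                budget = _plan_minutes(person, wave, config, rng)
                if sum(budget.values()) * 60 > day_len_s:
                    raise ValueError(
                        f"daily travel request {sum(budget.values()):.0f} min exceeds the "
                        f"{config.waking_hours:.0f}-h waking day"
                    )
                legs = _build_legs(
                    budget, g, nodes, home_node, under_pts, over_pts, rail_coords, config, rng
                )
                travel_s = sum(d for _, d, _, _ in legs)
                lead_s = _round10(max(0.0, (day_len_s - travel_s)) * 0.5)
                tail_s = int(day_len_s - travel_s - lead_s)
                t = t0
                seq = [("stationary_in", lead_s, home, 0.0), *legs, ("stationary_in", tail_s, home, 0.0)]
                for mode, dur_s, path, speed in seq:
                    if dur_s <= 0:
                        continue
                    end = t + pd.Timedelta(seconds=int(dur_s))
                    episodes.append(
                        DiaryEpisode(person["participant_id"], wave, day, t, end, mode, path, speed)
                    )
                    t = end
    return episodes


def _plan_minutes(person, wave: str, config: SimConfig, rng: np.random.Generator) -> dict[str, float]:
    """Target travel minutes per mode for one day, with the true effect injected."""
    at_followup = wave == "followup"
    is_ev = person["group"] == "EastVillage"
    out = {}
    for mode in TRAVEL_MODES:
        mu = float(config.category_means[mode])
        if is_ev and at_followup:
            mu += config.effect(mode, person["housing_group"])
        val = rng.normal(mu, config.day_sd_frac * float(config.category_means[mode]))
        out[mode] = max(0.0, val)
    return out


def _build_legs(budget, g, nodes, home_node, under_pts, over_pts, rail_coords, config, rng):
    legs: list[tuple[str, int, LineString | Point, float]] = []
    for mode in ("walking", "cycling", "vehicle"):
        minutes = budget[mode]
        if minutes < 0.5:
            continue
        dur_s = _round10(minutes * 60)
        lo, hi = config.speed_kmh[mode]
        speed = rng.uniform(lo, hi) / 3.6
        dst = nodes[int(rng.integers(len(nodes)))]
        coords = shortest_path_coords(g, home_node, dst)
        if len(coords) < 2:
            coords = shortest_path_coords(g, home_node, nodes[int(rng.integers(len(nodes)))])
        path = _traversal(coords, speed * dur_s)
        legs.append((mode, dur_s, path, speed))
    if budget["overground"] >= 0.5 and rail_coords and len(over_pts) >= 2:
        dur_s = _round10(budget["overground"] * 60)
        lo, hi = config.speed_kmh["overground"]
        speed = rng.uniform(lo, hi) / 3.6
        i, j = rng.choice(len(over_pts), size=2, replace=False)
        a, b = over_pts[i], over_pts[j]
        path = _traversal([(a.x, a.y), (b.x, b.y)], speed * dur_s)
        legs.append(("overground", dur_s, path, speed))
    if budget["underground"] >= 0.5 and len(under_pts) >= 2:
        dur_s = _round10(budget["underground"] * 60)
        dur_s = int(min(dur_s, config.max_gap_s - 600))  # keep within the gap rule window
        i, j = rng.choice(len(under_pts), size=2, replace=False)
        a, b = under_pts[i], under_pts[j]
        legs.append(("stationary_out", STATION_DWELL_S, a, 0.0))
        legs.append(("underground", dur_s, LineString([(a.x, a.y), (b.x, b.y)]), 0.0))
        legs.append(("stationary_out", STATION_DWELL_S, b, 0.0))
    return legs


def diaries_frame(episodes: list[DiaryEpisode]) -> pd.DataFrame:
    """Flat table view (path geometry as WKT) for the delimited-file interface."""
    return pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in episodes],
            "wave": [e.wave for e in episodes],
            "day": [e.day for e in episodes],
            "start": [e.start for e in episodes],
            "end": [e.end for e in episodes],
            "true_mode": [e.true_mode for e in episodes],
            "path_wkt": [e.path.wkt for e in episodes],
        }
    )
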