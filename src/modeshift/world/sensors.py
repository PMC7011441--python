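"""Raw sensor emulation: 10-s GPS fixes and 10-s accelerometer count epochs.

Accelerometer output covers the full 24-h day (zero counts outside the
waking window, so the wear-time algorithm sees a realistic sleep non-wear
block). GPS fixes are emitted on the same 10-s grid, with positional noise,
suppressed entirely during underground legs and with a configurable
dropout probability while stationary indoors.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from modeshift.config import SimConfig
from modeshift.world.diaries import DiaryEpisode

EPOCH_S = 10


class SensorStreams(NamedTuple):
    fixes: pd.DataFrame  # participant_id, wave, timestamp, x, y
    accel: pd.DataFrame  # participant_id, wave, timestamp, counts, vm_counts
    truth: pd.DataFrame  # participant_id, wave, timestamp, true_mode


def _epoch_range(start: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
    """10-s slot starts covering [start, end), aligned to midnight."""
    first = start.ceil(f"{EPOCH_S}s")
    if first >= end:
        return pd.DatetimeIndex([])
    return pd.date_range(first, end - pd.Timedelta(seconds=1), freq=f"{EPOCH_S}s")


def _draw_counts(mode: str, n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mean, sd, p_zero = config.count_params[mode]
    vals = np.maximum(0.0, rng.normal(mean, sd, size=n))
    vals[rng.random(n) < p_zero] = 0.0
    return np.round(vals)


def emulate_sensors(
    episodes: list[DiaryEpisode], config: SimConfig, *, rng: np.random.Generator | None = None
) -> SensorStreams:
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fix_rows, accel_rows, truth_rows = [], [], []
    covered: dict[tuple, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}

    for ep in episodes:
        slots = _epoch_range(ep.start, ep.end)
        n = len(slots)
        if n == 0:
            continue
        key = (ep.participant_id, ep.wave, ep.start.normalize())
        covered.setdefault(key, []).append((ep.start, ep.end))

        mode_key = ep.true_mode if ep.true_mode in config.count_params else "stationary_out"
        counts = _draw_counts(mode_key, n, config, rng)
        # vector magnitude runs a little above the vertical axis
        vm = np.round(counts * rng.uniform(1.15, 1.35, size=n))
        accel_rows.append(
            pd.DataFrame(
                {
                    "participant_id": ep.participant_id,
                    "wave": ep.wave,
                    "timestamp": slots,
                    "counts": counts,
                    "vm_counts": vm,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {"participant_id": ep.participant_id, "wave": ep.wave, "timestamp": slots, "true_mode": ep.true_mode}
            )
        )

        if ep.true_mode == "underground":
            continue  # total dropout: no fixes between the station endpoints
        if isinstance(ep.path, Point):
            xs = np.full(n, ep.path.x)
            ys = np.full(n, ep.path.y)
        else:
            path: LineString = ep.path
            elapsed = (slots - ep.start).total_seconds().to_numpy()
            frac = np.clip(elapsed / max(ep.duration_s, 1e-9), 0.0, 1.0)
            pts = [path.interpolate(f, normalized=True) for f in frac]
            xs = np.array([p.x for p in pts])
            ys = np.array([p.y for p in pts])
        keep = np.ones(n, dtype=bool)
        if ep.true_mode == "stationary_in":
            keep = rng.random(n) >= config.indoor_dropout_prob
        if keep.any():
            noise = rng.normal(0.0, config.gps_noise_sd_m, size=(n, 2))
            fix_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": ep.participant_id,
                        "wave": ep.wave,
                        "timestamp": slots[keep],
                        "x": xs[keep] + noise[keep, 0],
                        "y": ys[keep] + noise[keep, 1],
                    }
                )
            )

    accel = pd.concat(accel_rows, ignore_index=True) if accel_rows else _empty_accel()
    truth = pd.concat(truth_rows, ignore_index=True) if truth_rows else _empty_truth()
    fixes = pd.concat(fix_rows, ignore_index=True) if fix_rows else _empty_fixes()

    # pad each covered day with zero-count sleep epochs outside the waking window
    pads = []
    for (pid, wave, day0), spans in covered.items():
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        before = _epoch_range(day0, lo)
        after = _epoch_range(hi, day0 + pd.Timedelta(days=1))
        for slots in (before, after):
            if len(slots):
                pads.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "wave": wave,
                            "timestamp": slots,
                            "counts": 0.0,
                            "vm_counts": 0.0,
                        }
                    )
                )
    if pads:
        accel = pd.concat([accel, *pads], ignore_index=True)
    accel = accel.sort_values(["participant_id", "wave", "timestamp"], ignore_index=True)
    fixes = fixes.sort_values(["participant_id", "wave", "timestamp"], ignore_index=True)
    truth = truth.sort_values(["participant_id", "wave", "timestamp"], ignore_index=True)
    return SensorStreams(fixes=fixes, accel=accel, truth=truth)


def _empty_fixes() -> pd.DataFrame:
    return pd.DataFrame(columns=["participant_id", "wave", "timestamp", "x", "y"])


def _empty_accel() -> pd.DataFrame:
    return pd.DataFrame(columns=["participant_id", "wave", "timestamp", "counts"])


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame(columns=["participant_id", "wave", "timestamp", "true_mode"])
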