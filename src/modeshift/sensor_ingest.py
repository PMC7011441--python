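"""Raw stream ingest: GPS fixes, accelerometer epochs, wear time, valid days.

The fusion grid is the accelerometer's: one record per 10-s slot (aligned
to local midnight) from the first to the last accelerometer epoch. A GPS
fix is attached to the half-open slot [t, t+10) containing its timestamp;
epoch speed is the planar distance from the previously attached fix
divided by the inter-fix time.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd

from modeshift.geo import LocalProjection

logger = logging.getLogger(__name__)

EPOCH_S = 10


@dataclass(frozen=True)
class DayValidity:
    participant_id: str
    wave: str
    date: pd.Timestamp
    accel_wear_min: float
    gps_min: float
    valid: bool


# ---------------------------------------------------------------- GPS input


def read_gps(
    source: str | Path | io.IOBase,
    *,
    fmt: str | None = None,
    projection: LocalProjection | None = None,
) -> pd.DataFrame:
    """Read GPS fixes from GPX 1.1 or a delimited table.

    Returns a frame sorted by time with duplicate timestamps collapsed to
    the first occurrence. Lat/lon inputs are projected to metric ``x, y``
    when a projection is supplied; otherwise lat/lon are kept and callers
    must use haversine distances.
    """
    if fmt is None:
        fmt = "gpx" if str(source).lower().endswith(".gpx") else "delimited"
    if fmt == "gpx":
        fixes = _read_gpx(source)
    elif fmt == "delimited":
        fixes = _read_delimited(source)
    else:
        raise ValueError(f"unknown GPS format {fmt!r}")

    if fixes.empty:
        logger.warning("GPS source %s contained no parseable fixes", source)
        return fixes

    fixes = fixes.sort_values("timestamp", kind="stable")
    dups = fixes["timestamp"].duplicated().sum()
    if dups:
        logger.info("collapsed %d duplicate-timestamp fixes (kept first)", dups)
        fixes = fixes[~fixes["timestamp"].duplicated()]
    fixes = fixes.reset_index(drop=True)

    if projection is not None and "lat" in fixes.columns:
        xy = np.array([projection.to_xy(la, lo) for la, lo in zip(fixes["lat"], fixes["lon"])])
        fixes["x"], fixes["y"] = xy[:, 0], xy[:, 1]
    return fixes


def _read_gpx(source) -> pd.DataFrame:
    try:
        tree = ElementTree.parse(source)
    except (OSError, FileNotFoundError):
        raise
    except ElementTree.ParseError as exc:
        raise IOError(f"unreadable GPX {source}: {exc}") from exc
    rows, skipped = [], 0
    for pt in tree.getroot().iter():
        if not pt.tag.endswith("trkpt"):
            continue
        try:
            lat, lon = float(pt.attrib["lat"]), float(pt.attrib["lon"])
            t = next(c.text for c in pt if c.tag.endswith("time"))
            rows.append({"timestamp": pd.Timestamp(t).tz_localize(None), "lat": lat, "lon": lon})
        except (KeyError, StopIteration, ValueError):
            skipped += 1
    if skipped:
        logger.info("skipped %d unparseable trackpoints", skipped)
    return pd.DataFrame(rows, columns=["timestamp", "lat", "lon"])


def _read_delimited(source) -> pd.DataFrame:
    df = pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    if "timestamp" not in df.columns:
        raise IOError(f"{source}: delimited GPS table needs a 'timestamp' column")
    parsed = pd.to_datetime(df["timestamp"], format="mixed", errors="coerce", utc=True)
    bad = parsed.isna()
    if bad.any():
        logger.info("skipped %d rows with unparseable timestamps", int(bad.sum()))
    df = df[~bad].copy()
    df["timestamp"] = parsed[~bad].dt.tz_localize(None)
    return df.reset_index(drop=True)


def write_gpx(path: str | Path, fixes: pd.DataFrame, projection: LocalProjection) -> None:
    """Write metric fixes as a minimal single-track GPX 1.1 document."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<gpx version="1.1" creator="modeshift" xmlns="http://www.topografix.com/GPX/1/1">',
        "<trk><trkseg>",
    ]
    for _, row in fixes.iterrows():
        lat, lon = projection.to_latlon(row["x"], row["y"])
        t = pd.Timestamp(row["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
        lines.append(f'<trkpt lat="{lat:.7f}" lon="{lon:.7f}"><time>{t}</time></trkpt>')
    lines += ["</trkseg></trk>", "</gpx>"]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------- fusion


def fuse_epochs(fixes: pd.DataFrame, accel: pd.DataFrame) -> pd.DataFrame:
    """Join one participant-wave's streams onto the 10-s accelerometer grid.

    Returns columns: timestamp, counts, x, y, has_fix, speed (m/s, NaN when
    undefined), worn (all True here; wear bouts are annotated later).
    """
    if accel.empty:
        return pd.DataFrame(
            columns=["timestamp", "counts", "x", "y", "has_fix", "speed", "worn"]
        )
    acc = accel.copy()
    acc["timestamp"] = pd.to_datetime(acc["timestamp"]).dt.floor(f"{EPOCH_S}s")
    acc = acc.groupby("timestamp", as_index=False)["counts"].sum()
    grid = pd.date_range(acc["timestamp"].min(), acc["timestamp"].max(), freq=f"{EPOCH_S}s")
    rec = pd.DataFrame({"timestamp": grid})
    rec = rec.merge(acc, on="timestamp", how="left")
    rec["counts"] = rec["counts"].fillna(0.0)

    if not fixes.empty:
        fx = fixes.copy()
        fx["slot"] = pd.to_datetime(fx["timestamp"]).dt.floor(f"{EPOCH_S}s")
        fx = fx.groupby("slot", as_index=False).first()
        fx = fx.rename(columns={"timestamp": "fix_time"})
        rec = rec.merge(
            fx[["slot", "fix_time", "x", "y"]], left_on="timestamp", right_on="slot", how="left"
        ).drop(columns="slot")
    else:
        rec["fix_time"] = pd.NaT
        rec["x"] = np.nan
        rec["y"] = np.nan

    rec["has_fix"] = rec["x"].notna()
    rec["speed"] = _interfix_speed(rec)
    rec = rec.drop(columns="fix_time")
    rec["worn"] = True
    _conserve = float(rec["counts"].sum()) - float(accel["counts"].sum())
    if abs(_conserve) > 1e-6:
        raise AssertionError("fusion changed total accelerometer counts")
    return rec


def _interfix_speed(rec: pd.DataFrame) -> np.ndarray:
    speed = np.full(len(rec), np.nan)
    idx = np.flatnonzero(rec["has_fix"].to_numpy())
    if len(idx) < 2:
        return speed
    xs = rec["x"].to_numpy()[idx]
    ys = rec["y"].to_numpy()[idx]
    ts = rec["fix_time"].to_numpy()[idx].astype("datetime64[ns]").astype(np.int64) / 1e9
    d = np.hypot(np.diff(xs), np.diff(ys))
    dt = np.diff(ts)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt > 0, d / dt, np.nan)
    speed[idx[1:]] = v
    return speed


# ---------------------------------------------------------------- wear time


def wear_minutes(counts_by_minute: np.ndarray, nonwear_min: int = 60) -> float:
    """Minutes worn given per-minute total counts; non-wear is any run of
    >= ``nonwear_min`` consecutive zero-count minutes."""
    n = len(counts_by_minute)
    if n == 0:
        return 0.0
    zero = counts_by_minute == 0
    nonwear = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i >= nonwear_min:
                nonwear[i:j] = True
            i = j
        else:
            i += 1
    return float(n - nonwear.sum())


def wear_time(
    records: pd.DataFrame,
    date: pd.Timestamp,
    *,
    participant_id: str = "",
    wave: str = "",
    nonwear_min: int = 60,
    valid_day_min: int = 540,
) -> DayValidity:
    """Wear minutes and the >=540-min validity flag for one calendar day."""
    date = pd.Timestamp(date).normalize()
    day = records[
        (records["timestamp"] >= date) & (records["timestamp"] < date + pd.Timedelta(days=1))
    ]
    if day.empty:
        return DayValidity(participant_id, wave, date, 0.0, 0.0, False)
    per_min = day.groupby(day["timestamp"].dt.floor("min"))["counts"].sum()
    wear = wear_minutes(per_min.to_numpy(), nonwear_min)
    gps_min = float(day["has_fix"].sum()) * EPOCH_S / 60.0
    return DayValidity(participant_id, wave, date, wear, gps_min, wear >= valid_day_min)


def day_validity_table(
    records: pd.DataFrame,
    *,
    participant_id: str = "",
    wave: str = "",
    nonwear_min: int = 60,
    valid_day_min: int = 540,
) -> pd.DataFrame:
    days = records["timestamp"].dt.normalize().unique()
    rows = [
        wear_time(
            records,
            d,
            participant_id=participant_id,
            wave=wave,
            nonwear_min=nonwear_min,
            valid_day_min=valid_day_min,
        )
        for d in sorted(days)
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def filter_valid_days(records: pd.DataFrame, validity: pd.DataFrame) -> pd.DataFrame:
    """Keep epoch records only for days whose accelerometer validity holds.

    A valid accelerometer day with zero GPS fixes is retained (it will
    contribute zero-minute GPS categories); inclusion conditions only on
    accelerometry.
    """
    valid_dates = set(validity.loc[validity["valid"], "date"])
    keep = records["timestamp"].dt.normalize().isin(valid_dates)
    return records[keep].reset_index(drop=True)
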