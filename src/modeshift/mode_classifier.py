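"""Per-epoch travel-mode assignment.

Two interchangeable classifiers share one feature set: a deterministic
rule cascade (speed bands + accelerometer counts + rail-corridor
proximity) that acts as the oracle and fallback, and a gradient-boosted
tree model trained on synthetic labelled epochs. Epochs with no GPS in
their feature window are labelled stationary while worn; signal-loss gap
handling is a separate stage.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from modeshift.config import CLASSIFIER_MODES

EPOCH_S = 10

FEATURE_COLUMNS = (
    "speed_median",
    "speed_p95",
    "accel",
    "counts",
    "counts_window_mean",
    "rail_dist_m",
    "fix_fraction",
)


@dataclass
class RuleThresholds:
    """Speed bands in m/s; count floors are per-10-s window means."""

    stationary_max: float = 0.2
    walking_max: float = 2.0
    cycling_max: float = 7.0
    walk_count_floor: float = 100.0
    cycle_count_floor: float = 150.0
    rail_corridor_m: float = 50.0


@dataclass
class ModelArtifact:
    model: HistGradientBoostingClassifier
    feature_columns: tuple[str, ...]
    classes: tuple[str, ...]
    report: pd.DataFrame
    version: str = "1"

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "ModelArtifact":
        art = pickle.loads(Path(path).read_bytes())
        if not isinstance(art, cls):
            raise ValueError(f"{path} is not a classifier artifact")
        return art


def extract_features(
    records: pd.DataFrame,
    *,
    window_s: int = 60,
    rail_lines: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sliding-window features per epoch, computed separately per calendar day.

    One row per epoch that has at least one fix inside its (symmetric,
    day-truncated) window. ``records`` is one participant-wave's fused
    epoch table.
    """
    if window_s % EPOCH_S:
        raise ValueError("window_s must be a multiple of 10")
    w = max(1, window_s // EPOCH_S) | 1  # odd epoch count, centred
    out = []
    for _, day in records.groupby(records["timestamp"].dt.normalize(), sort=True):
        day = day.sort_values("timestamp")
        roll = lambda s, fn: s.rolling(w, center=True, min_periods=1).agg(fn)  # noqa: E731
        feats = pd.DataFrame(
            {
                "timestamp": day["timestamp"].to_numpy(),
                "speed_median": roll(day["speed"], "median").to_numpy(),
                "speed_p95": day["speed"].rolling(w, center=True, min_periods=1).quantile(0.95).to_numpy(),
                "counts": day["counts"].to_numpy(),
                "counts_window_mean": roll(day["counts"], "mean").to_numpy(),
                "fix_fraction": roll(day["has_fix"].astype(float), "mean").to_numpy(),
            }
        )
        feats["accel"] = pd.Series(feats["speed_median"]).diff().to_numpy() / EPOCH_S
        has_window_fix = (
            day["has_fix"].astype(float).rolling(w, center=True, min_periods=1).max().to_numpy() > 0
        )
        feats["rail_dist_m"] = _rail_distance(day, rail_lines)
        out.append(feats[has_window_fix])
    if not out:
        return pd.DataFrame(columns=["timestamp", *FEATURE_COLUMNS])
    return pd.concat(out, ignore_index=True)[["timestamp", *FEATURE_COLUMNS]]


def _rail_distance(day: pd.DataFrame, rail_lines: pd.DataFrame | None) -> np.ndarray:
    if rail_lines is None or len(rail_lines) == 0:
        return np.full(len(day), np.inf)
    pts = shapely.points(
        np.nan_to_num(day["x"].to_numpy(), nan=1e9), np.nan_to_num(day["y"].to_numpy(), nan=1e9)
    )
    dists = np.min(
        np.stack([shapely.distance(pts, line) for line in rail_lines["geometry"]]), axis=0
    )
    dists[~day["has_fix"].to_numpy()] = np.nan
    # carry the last known distance through short fix droughts
    return pd.Series(dists).ffill().bfill().fillna(np.inf).to_numpy()


def rule_classify(features: pd.DataFrame, thresholds: RuleThresholds | None = None) -> pd.DataFrame:
    """Deterministic cascade over speed bands, count floors and rail proximity."""
    th = thresholds or RuleThresholds()
    v = features["speed_median"].to_numpy()
    c = features["counts_window_mean"].to_numpy()
    r = features["rail_dist_m"].to_numpy()

    mode = np.full(len(features), "stationary", dtype=object)
    moving = np.isfinite(v) & (v >= th.stationary_max)
    slow = moving & (v < th.walking_max)
    mid = moving & (v >= th.walking_max) & (v < th.cycling_max)
    fast = moving & (v >= th.cycling_max)

    mode[slow & (c >= th.walk_count_floor)] = "walking"
    mode[slow & (c < th.walk_count_floor)] = "vehicle"
    mode[mid & (c >= th.cycle_count_floor)] = "cycling"
    mode[mid & (c < th.cycle_count_floor)] = "vehicle"
    mode[fast & (r <= th.rail_corridor_m)] = "overground"
    mode[fast & (r > th.rail_corridor_m)] = "vehicle"
    return pd.DataFrame({"timestamp": features["timestamp"], "mode": mode, "source": "rule"})


def train_model(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int,
    *,
    n_trees: int = 500,
    max_depth: int = 3,
    learning_rate: float = 0.05,
    holdout_frac: float = 0.25,
) -> ModelArtifact:
    """Fit gradient-boosted trees on labelled epochs; report held-out metrics."""
    y = np.asarray(labels)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    X = np.where(np.isinf(X), 1e6, X)
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=holdout_frac, random_state=seed, stratify=y
    )
    model = HistGradientBoostingClassifier(
        max_iter=n_trees, max_depth=max_depth, learning_rate=learning_rate, random_state=seed
    )
    model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    prec, rec, f1, support = precision_recall_fscore_support(
        yte, pred, labels=list(classes), zero_division=0
    )
    report = pd.DataFrame(
        {"class": classes, "precision": prec, "recall": rec, "f1": f1, "support": support}
    )
    report.attrs["holdout_accuracy"] = float((pred == yte).mean())
    return ModelArtifact(model=model, feature_columns=FEATURE_COLUMNS, classes=classes, report=report)


def classify(
    records: pd.DataFrame,
    classifier: ModelArtifact | str,
    *,
    window_s: int = 60,
    rail_lines: pd.DataFrame | None = None,
    thresholds: RuleThresholds | None = None,
) -> pd.DataFrame:
    """Label every worn epoch; no-GPS-window epochs become stationary.

    ``classifier`` is a trained :class:`ModelArtifact` or the string
    ``"rule"``.
    """
    if records.empty:
        return pd.DataFrame(columns=["timestamp", "mode", "source"])
    feats = extract_features(records, window_s=window_s, rail_lines=rail_lines)
    if isinstance(classifier, str):
        if classifier != "rule":
            raise ValueError("classifier must be a ModelArtifact or 'rule'")
        labelled = rule_classify(feats, thresholds)
    else:
        X = feats[list(classifier.feature_columns)].to_numpy(dtype=float)
        X = np.where(np.isinf(X), 1e6, X)
        pred = classifier.model.predict(X) if len(X) else np.array([], dtype=object)
        labelled = pd.DataFrame({"timestamp": feats["timestamp"], "mode": pred, "source": "model"})

    out = records[["timestamp", "worn"]].merge(labelled, on="timestamp", how="left")
    missing = out["mode"].isna()
    out.loc[missing & out["worn"], "mode"] = "stationary"
    out.loc[missing, "source"] = "no_gps"
    out = out[out["mode"].notna()]
    bad = set(out["mode"]) - set(CLASSIFIER_MODES)
    if bad:
        raise AssertionError(f"classifier emitted unknown modes: {bad}")
    return out[["timestamp", "mode", "source"]].reset_index(drop=True)


def smooth_labels(labels: pd.DataFrame, min_run_s: int = 30) -> pd.DataFrame:
    """Absorb runs shorter than ``min_run_s`` into the longer neighbouring run.

    Shortest runs are resolved first (ties by position); a tie between
    neighbours goes to the earlier one. Idempotent by construction: the
    loop only exits when no short run remains.
    """
    if min_run_s % EPOCH_S:
        raise ValueError("min_run_s must be a multiple of 10")
    min_len = min_run_s // EPOCH_S
    if labels.empty:
        return labels.copy()
    out = labels.sort_values("timestamp").reset_index(drop=True)
    modes = list(out["mode"])
    runs = _runs(modes)
    while len(runs) > 1:
        short = [(ln, i) for i, (_, ln) in enumerate(runs) if ln < min_len]
        if not short:
            break
        _, i = min(short)
        left = runs[i - 1][1] if i > 0 else -1
        right = runs[i + 1][1] if i + 1 < len(runs) else -1
        j = i - 1 if left >= right else i + 1
        runs[i] = (runs[j][0], runs[i][1])
        runs = _merge_adjacent(runs)
    smoothed = [m for m, ln in runs for _ in range(ln)]
    changed = np.array(smoothed) != np.array(modes)
    out["mode"] = smoothed
    out.loc[changed, "source"] = "smoothed"
    return out


def _runs(modes: list) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for m in modes:
        if runs and runs[-1][0] == m:
            runs[-1] = (m, runs[-1][1] + 1)
        else:
            runs.append((m, 1))
    return runs


def _merge_adjacent(runs: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for m, ln in runs:
        if merged and merged[-1][0] == m:
            merged[-1] = (m, merged[-1][1] + ln)
        else:
            merged.append((m, ln))
    return merged
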