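"""Simulation and pipeline configuration.

A single :class:`SimConfig` drives both fidelity levels of the synthetic
generator: ``epoch`` (full sensor emulation, used to exercise the ingest /
classification / gap stages) and ``day`` (direct day-level minute draws,
used for statistical recovery at full cohort size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

#: Motion categories, in reporting order. ``walking + cycling`` is derived
#: downstream as "active travel"; it is not a primary category.
CATEGORIES = ("walking", "cycling", "vehicle", "overground", "underground", "stationary")

#: Travel modes the classifier can emit (stationary folded in).
CLASSIFIER_MODES = ("walking", "cycling", "vehicle", "overground", "stationary")

#: Default daily minutes per category for the day-level generator
#: (all-housing control-arm means of the study this pipeline emulates).
DEFAULT_CATEGORY_MEANS: dict[str, float] = {
    "walking": 39.7,
    "cycling": 6.1,
    "vehicle": 37.3,
    "overground": 14.6,
    "underground": 14.3,
    "stationary": 440.0,
}

#: Default housing-group mixing proportions (social / intermediate / market-rent).
DEFAULT_HOUSING_COUNTS = (201, 283, 94)

HOUSING_GROUPS = ("social", "intermediate", "market_rent")
AGE_GROUPS = ("16-24", "25-34", "35-49", "50+")
ETHNIC_GROUPS = ("White", "Black", "Asian", "Other")
SEXES = ("female", "male")
GROUPS = ("Control", "EastVillage")

#: Speed bands per mode in km/h; the source study reports none, so these are
#: config-exposed defaults.
DEFAULT_SPEED_KMH: dict[str, tuple[float, float]] = {
    "walking": (3.0, 6.0),
    "cycling": (10.0, 25.0),
    "vehicle": (15.0, 60.0),
    "overground": (30.0, 80.0),
    "underground": (30.0, 60.0),
}

#: Accelerometer 10-s count distributions per mode: (mean, sd) of a gamma-ish
#: draw plus a zero-inflation probability. Counts are arbitrary device units.
DEFAULT_COUNT_PARAMS: dict[str, tuple[float, float, float]] = {
    "walking": (600.0, 150.0, 0.0),
    "cycling": (350.0, 120.0, 0.02),
    "vehicle": (60.0, 40.0, 0.20),
    "overground": (60.0, 40.0, 0.20),
    "underground": (60.0, 40.0, 0.20),
    "stationary_in": (25.0, 25.0, 0.55),
    "stationary_out": (45.0, 35.0, 0.40),
}


@dataclass
class SimConfig:
    """Everything the synthetic generators need, with study-scale defaults."""

    seed: int = 0
    n_participants: int = 578
    n_households: int = 400
    fidelity: str = "day"  # "epoch" | "day"
    wear_days: int = 7
    ev_household_prob: float = 0.5
    housing_counts: tuple[int, int, int] = DEFAULT_HOUSING_COUNTS

    # --- day-level generator ---
    category_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MEANS))
    #: EastVillage-minus-Control difference in change, min/day. Either a flat
    #: ``{category: effect}`` or nested ``{category: {housing_group: effect}}``.
    true_effects: Mapping[str, object] = field(default_factory=dict)
    #: Noise scales as fractions of each category mean.
    household_sd_frac: float = 0.12
    person_sd_frac: float = 0.18
    day_sd_frac: float = 0.20

    # --- epoch-level generator ---
    day_start_hour: float = 8.0
    waking_hours: float = 16.0
    gps_noise_sd_m: float = 5.0
    indoor_dropout_prob: float = 0.85
    speed_kmh: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_SPEED_KMH))
    count_params: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUNT_PARAMS)
    )

    # --- ingest / rules ---
    nonwear_min: int = 60
    valid_day_min: int = 540
    min_gap_s: int = 120
    max_gap_s: int = 7200
    station_radius_m: float = 200.0
    gap_endpoint_mode: str = "both_endpoints_distinct"  # or "either_endpoint"

    def __post_init__(self) -> None:
        if self.fidelity not in ("epoch", "day"):
            raise ValueError(f"fidelity must be 'epoch' or 'day', got {self.fidelity!r}")
        if self.n_households > self.n_participants:
            raise ValueError(
                f"n_households ({self.n_households}) exceeds n_participants ({self.n_participants})"
            )
        if not 1 <= self.wear_days <= 7:
            raise ValueError("wear_days must be in 1..7")
        if not 0.0 <= self.indoor_dropout_prob <= 1.0:
            raise ValueError("indoor_dropout_prob must be a probability")
        for frac in (self.household_sd_frac, self.person_sd_frac, self.day_sd_frac):
            if frac < 0:
                raise ValueError("noise scales must be non-negative")

    def effect(self, category: str, housing_group: str | None = None) -> float:
        """Resolve the configured true effect for a category (optionally per stratum)."""
        raw = self.true_effects.get(category, 0.0)
        if isinstance(raw, Mapping):
            if housing_group is None:
                raise ValueError(f"effect for {category!r} is stratum-specific; pass housing_group")
            return float(raw.get(housing_group, 0.0))
        return float(raw)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in SimConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "housing_counts" in data:
        data["housing_counts"] = tuple(data["housing_counts"])
    return SimConfig(**data)
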