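"""Synthetic cohort: households, covariates, group assignment, addresses.

Group (intervention vs control) and housing group are household-level
attributes; everyone in a household shares them, along with both addresses.
Raw covariates deliberately include the categories the covariate encoder
has to collapse (``Mixed`` ethnicity, occupation strings, student status).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point

from modeshift.config import SimConfig
from modeshift.world.city import CityLayers

_RAW_ETHNICITIES = ("White", "Black", "Asian", "Mixed", "Other")
_RAW_ETHNICITY_P = (0.54, 0.22, 0.15, 0.05, 0.04)
_OCCUPATIONS = (
    "higher managerial or professional",
    "intermediate occupation",
    "routine or manual occupation",
    "student",
    "unemployed",
    "retired",
    "looking after home or family",
)
_OCCUPATION_P = (0.42, 0.17, 0.11, 0.12, 0.08, 0.04, 0.06)


def generate_cohort(
    city: CityLayers | None, config: SimConfig, *, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One row per participant; household-level fields are shared within household.

    ``city`` may be ``None`` for day-fidelity simulation, in which case no
    addresses are assigned.
    """
    if config.n_households > config.n_participants:
        raise ValueError("n_households may not exceed n_participants")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, nh = config.n_participants, config.n_households

    # Round-robin membership: household sizes differ by at most one, so a
    # cohort of 2k people in k households is exactly 2 per household.
    household = rng.permutation(np.arange(n) % nh)

    hcounts = np.asarray(config.housing_counts, dtype=float)
    hh_housing = rng.choice(len(hcounts), size=nh, p=hcounts / hcounts.sum())
    hh_group = np.where(rng.random(nh) < config.ev_household_prob, "EastVillage", "Control")

    housing_names = np.array(["social", "intermediate", "market_rent"])
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "household_id": [f"H{h:04d}" for h in household],
            "group": hh_group[household],
            "housing_group": housing_names[hh_housing[household]],
            "sex": rng.choice(["female", "male"], size=n, p=[0.57, 0.43]),
            "age_years": rng.integers(16, 75, size=n),
            "ethnicity_raw": rng.choice(_RAW_ETHNICITIES, size=n, p=_RAW_ETHNICITY_P),
            "occupation_raw": rng.choice(_OCCUPATIONS, size=n, p=_OCCUPATION_P),
        }
    )
    df["working_studying"] = df["occupation_raw"].isin(
        ["higher managerial or professional", "intermediate occupation", "routine or manual occupation", "student"]
    )

    if city is not None:
        _assign_addresses(df, city, rng)
    return df


def _assign_addresses(df: pd.DataFrame, city: CityLayers, rng: np.random.Generator) -> None:
    res = city.parcels[city.parcels["land_use"] == "residential"]
    if res.empty:
        raise ValueError("city has no residential parcels to place households in")
    centroids = [g.centroid for g in res["geometry"]]
    inside = np.array([city.target_district.contains(c) for c in centroids])
    out_pts = [c for c, i in zip(centroids, inside) if not i]
    in_pts = [c for c, i in zip(centroids, inside) if i]
    if not out_pts or not in_pts:
        raise ValueError("need residential parcels both inside and outside the target district")

    households = df["household_id"].unique()
    base = {h: out_pts[rng.integers(len(out_pts))] for h in households}
    follow = {}
    for h in households:
        grp = df.loc[df["household_id"] == h, "group"].iloc[0]
        if grp == "EastVillage":
            follow[h] = in_pts[rng.integers(len(in_pts))]
        elif rng.random() < 0.1:  # a few controls move, but never into the district
            follow[h] = out_pts[rng.integers(len(out_pts))]
        else:
            follow[h] = base[h]
    df["home_x_baseline"] = [base[h].x for h in df["household_id"]]
    df["home_y_baseline"] = [base[h].y for h in df["household_id"]]
    df["home_x_followup"] = [follow[h].x for h in df["household_id"]]
    df["home_y_followup"] = [follow[h].y for h in df["household_id"]]


def address_points(cohort: pd.DataFrame, wave: str) -> list[Point]:
    """Shapely points for one wave's home addresses (epoch-fidelity cohorts only)."""
    xs = cohort[f"home_x_{wave}"]
    ys = cohort[f"home_y_{wave}"]
    return [Point(x, y) for x, y in zip(xs, ys)]
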