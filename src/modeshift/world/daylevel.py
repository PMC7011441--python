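"""Day-level synthetic outcomes for statistical recovery runs.

Bypasses the sensor stages entirely: per participant-wave-day minutes in
each motion category are drawn from a three-level normal model

    minutes = category mean + household effect + person effect + day noise
              + true effect x 1[intervention group] x 1[follow-up wave]

with negatives truncated at zero. Noise SDs default to fixed fractions of
each category mean, small enough that truncation bias is negligible at the
default means (see tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from modeshift.config import CATEGORIES, SimConfig

BASELINE_START = pd.Timestamp("2014-05-05")  # a Monday
FOLLOWUP_START = pd.Timestamp("2016-05-02")  # also a Monday, two years on


def generate_day_level(
    cohort: pd.DataFrame, config: SimConfig, *, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One row per participant-wave-day with minutes in all six categories.

    Wear windows start on a per-participant random weekday offset so
    day-of-week composition varies across participants.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(cohort)
    d = config.wear_days
    households = cohort["household_id"].to_numpy()
    uniq_hh, hh_idx = np.unique(households, return_inverse=True)

    is_ev = (cohort["group"].to_numpy() == "EastVillage").astype(float)
    housing = cohort["housing_group"].to_numpy()
    start_offset = rng.integers(0, 7, size=n)

    frames = []
    for wave, wave_start in (("baseline", BASELINE_START), ("followup", FOLLOWUP_START)):
        day_order = np.tile(np.arange(1, d + 1), n)
        pid = np.repeat(np.arange(n), d)
        dates = wave_start + pd.to_timedelta(np.repeat(start_offset, d) + day_order - 1, unit="D")
        block = pd.DataFrame(
            {
                "participant_id": cohort["participant_id"].to_numpy()[pid],
                "household_id": households[pid],
                "group": cohort["group"].to_numpy()[pid],
                "housing_group": housing[pid],
                "wave": wave,
                "day_order": day_order,
                "date": dates,
            }
        )
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    pid_all = np.tile(np.repeat(np.arange(n), d), 2)
    at_followup = (out["wave"] == "followup").to_numpy().astype(float)

    for cat in CATEGORIES:
        mu = float(config.category_means[cat])
        hh_sd = config.household_sd_frac * mu
        pp_sd = config.person_sd_frac * mu
        dd_sd = config.day_sd_frac * mu
        b_hh = rng.normal(0.0, hh_sd, size=len(uniq_hh))
        b_pp = rng.normal(0.0, pp_sd, size=n)
        eff = np.array([config.effect(cat, hg) for hg in housing])
        y = (
            mu
            + b_hh[hh_idx[pid_all]]
            + b_pp[pid_all]
            + rng.normal(0.0, dd_sd, size=len(out))
            + eff[pid_all] * is_ev[pid_all] * at_followup
        )
        out[cat] = np.maximum(y, 0.0)
    return out
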