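"""Daily category minutes and residual-adjusted per-participant averages.

The adjusted average follows a two-level recipe: day-level minutes are
regressed on day-order-of-wear, day-of-week and month (fixed effects)
with the participant as a random effect; each participant's estimate is
the grand mean of the fitted values plus the mean of that participant's
residuals from the fixed-effects prediction. In a balanced design with no
covariate effects this reduces to the participant's raw day mean.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from modeshift.config import CATEGORIES
from modeshift.underground_gaps import SignalGap, epochs_in_flagged_gaps, gap_minutes_by_day

logger = logging.getLogger(__name__)

EPOCH_S = 10
PROFILE_CATEGORIES = CATEGORIES  # walking..stationary
DERIVED = ("active_travel", "total_gps_min")


def summarise_days(
    labels: pd.DataFrame,
    gaps: list[SignalGap],
    validity: pd.DataFrame,
    *,
    participant_id: str = "",
    wave: str = "",
) -> pd.DataFrame:
    """Sum one participant-wave's labelled epochs into per-day category minutes.

    Only accelerometer-valid days are kept. Flagged-gap minutes become
    underground minutes; epochs lying inside a flagged gap are excluded
    from every other tally (no double counting).
    """
    valid_dates = sorted(validity.loc[validity["valid"], "date"])
    if labels.empty and not valid_dates:
        return _empty_profiles()

    # Epochs inside flagged gaps (labelled stationary for lack of GPS, or by
    # windowed features near the gap edges) are dropped so their time is
    # counted once, as underground gap minutes.
    lab = labels[~epochs_in_flagged_gaps(labels, gaps)].copy()
    lab["date"] = lab["timestamp"].dt.normalize()

    per_day = (
        lab.groupby(["date", "mode"]).size().unstack(fill_value=0).astype(float) * EPOCH_S / 60.0
    )
    gap_min = gap_minutes_by_day(gaps).set_index("date")["underground_min"] if gaps else pd.Series(dtype=float)

    rows = []
    for order, date in enumerate(valid_dates, start=1):
        day = per_day.loc[date] if date in per_day.index else pd.Series(dtype=float)
        row = {
            "participant_id": participant_id,
            "wave": wave,
            "date": date,
            "day_order": order,
            "day_of_week": pd.Timestamp(date).dayofweek,
            "month": pd.Timestamp(date).month,
            "walking": float(day.get("walking", 0.0)),
            "cycling": float(day.get("cycling", 0.0)),
            "vehicle": float(day.get("vehicle", 0.0)),
            "overground": float(day.get("overground", 0.0)),
            "underground": float(gap_min.get(date, 0.0)),
            "stationary": float(day.get("stationary", 0.0)),
        }
        rows.append(row)
    if not rows:
        return _empty_profiles()
    out = add_derived(pd.DataFrame(rows))
    if (out["total_gps_min"] > 24 * 60 + 1e-6).any():
        raise RuntimeError("per-day minutes exceed 24 h: gap/epoch double-count")
    return out


def add_derived(profiles: pd.DataFrame) -> pd.DataFrame:
    out = profiles.copy()
    out["active_travel"] = out["walking"] + out["cycling"]
    out["total_gps_min"] = out[list(PROFILE_CATEGORIES)].sum(axis=1)
    return out


def _empty_profiles() -> pd.DataFrame:
    cols = [
        "participant_id",
        "wave",
        "date",
        "day_order",
        "day_of_week",
        "month",
        *PROFILE_CATEGORIES,
        *DERIVED,
    ]
    return pd.DataFrame(columns=cols)


def ensure_profile_columns(day_rows: pd.DataFrame) -> pd.DataFrame:
    """Add derived/calendar columns to generator or file input as needed."""
    out = day_rows.copy()
    if "day_of_week" not in out.columns:
        out["day_of_week"] = pd.to_datetime(out["date"]).dt.dayofweek
    if "month" not in out.columns:
        out["month"] = pd.to_datetime(out["date"]).dt.month
    if "active_travel" not in out.columns:
        out = add_derived(out)
    return out


def adjusted_daily_average(
    profiles: pd.DataFrame, category: str, *, floor_at_zero: bool = True
) -> pd.Series:
    """Residual-adjusted average daily minutes per participant for one wave.

    ``profiles`` must hold one wave only. Returns a Series indexed by
    participant_id.
    """
    if profiles["wave"].nunique() > 1:
        raise ValueError("pass a single wave's profiles")
    if profiles["participant_id"].nunique() < 2:
        raise ValueError("need at least two participants")

    terms = [
        f"C({col})"
        for col in ("day_order", "day_of_week", "month")
        if profiles[col].nunique() > 1
    ]
    df = profiles[["participant_id", "day_order", "day_of_week", "month", category]].copy()
    df = df.rename(columns={category: "y"})

    if terms:
        formula = "y ~ " + " + ".join(terms)
        fitted = _fixed_effect_fit(df, formula)
    else:
        fitted = np.full(len(df), df["y"].mean())

    population_mean = float(np.mean(fitted))
    resid = df["y"].to_numpy() - fitted
    est = population_mean + pd.Series(resid).groupby(df["participant_id"].to_numpy()).mean()
    est.index.name = "participant_id"
    if floor_at_zero:
        n_neg = int((est < 0).sum())
        if n_neg:
            logger.info("floored %d negative adjusted estimates at 0 (%s)", n_neg, category)
        est = est.clip(lower=0.0)
    return est


def _fixed_effect_fit(df: pd.DataFrame, formula: str) -> np.ndarray:
    """Fixed-effects predictions from the two-level model (participant as
    random intercept); falls back to OLS when the mixed fit is singular."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(formula, df, groups=df["participant_id"]).fit(reml=True)
        return np.asarray(m.predict(df))  # fixed-effects part only
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed fit failed (%s); falling back to fixed-effects OLS", exc)
        return np.asarray(smf.ols(formula, df).fit().predict(df))


def participant_wave_summary(
    profiles: pd.DataFrame,
    *,
    categories: tuple[str, ...] = (*PROFILE_CATEGORIES, *DERIVED),
    method: str = "adjusted",
) -> pd.DataFrame:
    """Wide table: one row per participant-wave, adjusted (or raw-mean)
    average daily minutes per category."""
    if method not in ("adjusted", "mean"):
        raise ValueError("method must be 'adjusted' or 'mean'")
    profiles = ensure_profile_columns(profiles)
    pieces = []
    for wave, sub in profiles.groupby("wave", sort=True):
        if method == "adjusted":
            block = pd.DataFrame(
                {cat: adjusted_daily_average(sub, cat) for cat in categories}
            )
        else:
            block = sub.groupby("participant_id")[list(categories)].mean()
        block.insert(0, "wave", wave)
        pieces.append(block.reset_index())
    return pd.concat(pieces, ignore_index=True)
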