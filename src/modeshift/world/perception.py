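"""Synthetic 14-item neighbourhood-perception responses from a 2-factor model.

Items are 4-point ordinal (1 worst .. 4 best), seven marking a perceived
crime/safety factor and seven a neighbourhood-quality factor. Movers get a
configurable latent improvement at follow-up, so downstream perception
change scores have a known sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CRIME_ITEMS = [f"crime_{i}" for i in range(1, 8)]
QUALITY_ITEMS = [f"quality_{i}" for i in range(1, 8)]
ITEMS = CRIME_ITEMS + QUALITY_ITEMS


def default_loadings(rng: np.random.Generator | None = None) -> np.ndarray:
    """14 x 2 generating loadings: simple structure with mild cross-loadings."""
    rng = rng if rng is not None else np.random.default_rng(0)
    L = np.zeros((14, 2))
    L[:7, 0] = rng.uniform(0.6, 0.85, 7)
    L[7:, 1] = rng.uniform(0.6, 0.85, 7)
    L[:7, 1] = rng.uniform(0.0, 0.15, 7)
    L[7:, 0] = rng.uniform(0.0, 0.15, 7)
    return L


def generate_perception_responses(
    cohort: pd.DataFrame,
    wave: str,
    *,
    rng: np.random.Generator,
    loadings: np.ndarray | None = None,
    factor_corr: float = 0.3,
    ev_followup_shift: tuple[float, float] = (1.0, 1.5),
    missing_prob: float = 0.01,
) -> pd.DataFrame:
    """Ordinal item responses for one wave, indexed by participant."""
    n = len(cohort)
    L = loadings if loadings is not None else default_loadings()
    cov = np.array([[1.0, factor_corr], [factor_corr, 1.0]])
    f = rng.multivariate_normal([0, 0], cov, size=n)
    if wave == "followup":
        is_ev = (cohort["group"] == "EastVillage").to_numpy()
        f[is_ev] += np.asarray(ev_followup_shift)
    latent = 2.5 + f @ L.T + rng.normal(0, 0.5, size=(n, 14))
    vals = np.clip(np.round(latent), 1, 4)
    vals[rng.random(vals.shape) < missing_prob] = np.nan
    return pd.DataFrame(vals, columns=ITEMS, index=cohort["participant_id"].to_numpy())
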