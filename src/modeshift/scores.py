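"""Neighbourhood-perception factor scores and covariate encoding.

Two factors (perceived crime, perceived quality) are extracted from 14
ordinal questionnaire items by exploratory factor analysis at baseline:
maximum-likelihood extraction, promax (oblique) rotation, regression-method
scoring. The baseline scoring weights are reapplied at follow-up so change
scores are on one scale. Items are oriented so that higher = safer/better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

logger = logging.getLogger(__name__)

N_ITEMS = 14
FACTOR_NAMES = ("crime_score", "quality_score")


# ------------------------------------------------------------- rotations


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    L = loadings.copy()
    p, k = L.shape
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        u, s, vt = np.linalg.svd(L.T @ (LR**3 - (LR * (LR**2).sum(axis=0)) / p))
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return L @ R


def promax(loadings: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation. Returns (pattern matrix, factor correlation)."""
    V = varimax(loadings)
    target = np.sign(V) * np.abs(V) ** power
    T, *_ = np.linalg.lstsq(V, target, rcond=None)
    T = T * np.sqrt(np.diag(np.linalg.inv(T.T @ T)))  # unit-variance factors
    pattern = V @ T
    T_inv = np.linalg.inv(T)
    phi = T_inv @ T_inv.T
    return pattern, phi


# ------------------------------------------------------------- fitting


@dataclass
class PerceptionWeights:
    """Baseline-fitted loadings and scoring weights, frozen for follow-up."""

    loadings: pd.DataFrame  # item x factor pattern matrix
    phi: np.ndarray  # factor correlation matrix
    weights: pd.DataFrame  # item x factor regression scoring weights
    item_means: pd.Series
    item_sds: pd.Series

    @property
    def items(self) -> list[str]:
        return list(self.loadings.index)


def fit_perception_factors(
    responses: pd.DataFrame, *, crime_items: list[str] | None = None
) -> PerceptionWeights:
    """Two-factor EFA on 14 baseline items.

    ``crime_items`` names the item subset expected to mark the crime
    factor; by default any column whose name contains ``crime``. Used only
    to *name* and orient the factors, never to constrain the fit.
    """
    items = list(responses.columns)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item columns, got {len(items)}")
    data = responses.dropna()
    if len(data) < 5 * N_ITEMS:
        raise ValueError(
            f"need at least {5 * N_ITEMS} complete respondents to fit factors, got {len(data)}"
        )
    if crime_items is None:
        crime_items = [c for c in items if "crime" in c.lower()] or items[: N_ITEMS // 2]

    means = data.mean()
    sds = data.std(ddof=1)
    if (sds <= 0).any():
        bad = list(sds[sds <= 0].index)
        raise ValueError(f"items with zero variance cannot be factored: {bad}")
    Z = ((data - means) / sds).to_numpy()

    fa = FactorAnalysis(n_components=2, svd_method="lapack")
    fa.fit(Z)
    if not np.isfinite(fa.components_).all():
        raise RuntimeError("factor extraction failed to converge; check item correlations")
    pattern, phi = promax(fa.components_.T)

    # Assign and orient factors: the one loading most on the crime items is
    # the crime factor, and each factor's dominant loadings are made positive
    # (items are coded so higher response = safer / better neighbourhood).
    crime_idx = [items.index(c) for c in crime_items]
    crime_mass = np.abs(pattern[crime_idx, :]).sum(axis=0)
    order = [int(np.argmax(crime_mass)), int(np.argmin(crime_mass))]
    if order[0] == order[1]:  # degenerate; keep given order
        order = [0, 1]
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    for j in range(2):
        dominant = np.abs(pattern[:, j]) > 0.3
        ref = pattern[dominant, j].sum() if dominant.any() else pattern[:, j].sum()
        if ref < 0:
            pattern[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1

    # Regression-method factor score coefficients: B = R^-1 (Lambda Phi)
    R = np.corrcoef(Z, rowvar=False)
    structure = pattern @ phi
    B = np.linalg.solve(R, structure)

    loadings = pd.DataFrame(pattern, index=items, columns=FACTOR_NAMES)
    weights = pd.DataFrame(B, index=items, columns=FACTOR_NAMES)
    return PerceptionWeights(loadings=loadings, phi=phi, weights=weights, item_means=means, item_sds=sds)


def score_perceptions(
    responses: pd.DataFrame, weights: PerceptionWeights, *, max_missing: int = 2
) -> pd.DataFrame:
    """Apply baseline weights; rows with more than ``max_missing`` missing
    items get missing scores. Missing items are imputed at the baseline item
    mean (z = 0)."""
    items = weights.items
    Z = (responses[items] - weights.item_means) / weights.item_sds
    n_missing = Z.isna().sum(axis=1)
    too_many = n_missing > max_missing
    if too_many.any():
        logger.info("%d respondents have >%d missing items; scores set missing", int(too_many.sum()), max_missing)
    scores = Z.fillna(0.0).to_numpy() @ weights.weights.to_numpy()
    out = pd.DataFrame(scores, index=responses.index, columns=FACTOR_NAMES)
    out[too_many] = np.nan
    return out


# ------------------------------------------------------------- covariates

_ETHNICITY_MAP = {
    "White": "White",
    "Black": "Black",
    "Asian": "Asian",
    "Mixed": "Other",  # Mixed and Other are combined in analysis
    "Other": "Other",
}

_NSSEC_MAP = {
    "higher managerial or professional": "higher_managerial_professional",
    "intermediate occupation": "intermediate",
    "routine or manual occupation": "routine_manual",
    # not part of the labour force -> economically inactive, students included
    "student": "economically_inactive",
    "unemployed": "economically_inactive",
    "retired": "economically_inactive",
    "looking after home or family": "economically_inactive",
    "unable to work": "economically_inactive",
}

AGE_BINS = ((16, 24, "16-24"), (25, 34, "25-34"), (35, 49, "35-49"), (50, 200, "50+"))


def encode_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Analysis covariates: age group, collapsed ethnic group, NS-SEC class,
    working/studying flag. Raises on unknown raw categories."""
    out = cohort.copy()

    ages = out["age_years"]
    bad_age = ages < 16
    if bad_age.any():
        raise ValueError(f"ages below 16 not encodable: {sorted(ages[bad_age].unique())}")
    out["age_group"] = pd.cut(
        ages,
        bins=[b[0] - 0.5 for b in AGE_BINS] + [200],
        labels=[b[2] for b in AGE_BINS],
    ).astype(str)

    unknown_eth = set(out["ethnicity_raw"]) - set(_ETHNICITY_MAP)
    if unknown_eth:
        raise ValueError(f"unknown ethnicity categories: {sorted(unknown_eth)}")
    out["ethnic_group"] = out["ethnicity_raw"].map(_ETHNICITY_MAP)

    unknown_occ = set(out["occupation_raw"]) - set(_NSSEC_MAP)
    if unknown_occ:
        raise ValueError(f"unknown occupation categories: {sorted(unknown_occ)}")
    out["nssec"] = out["occupation_raw"].map(_NSSEC_MAP)

    if "working_studying" not in out.columns:
        out["working_studying"] = out["occupation_raw"].isin(
            [k for k, v in _NSSEC_MAP.items() if v != "economically_inactive"] + ["student"]
        )
    return out
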