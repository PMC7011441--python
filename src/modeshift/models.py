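"""Household-clustered change models for the intervention effect.

For each motion category, the follow-up adjusted daily average is
regressed on its baseline value plus group, sex, age group, ethnic group
and (in the pooled model) housing group as fixed effects, with a
household random intercept, by REML. The group coefficient estimates the
average within-person change in the intervention group relative to
control. Wald 95% CIs throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from patsy import dmatrix

logger = logging.getLogger(__name__)

GROUP_TERM = "group[T.EastVillage]"
BASE_COVARIATES = ("sex", "age_group", "ethnic_group")


@dataclass
class EffectEstimate:
    outcome: str
    stratum: str  # "all" or a housing group
    n: int
    difference: float  # EV minus Control change, min/day
    ci_low: float
    ci_high: float
    p_value: float
    model: str = "mixed"  # "mixed" | "ols_fallback"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.difference <= self.ci_high:
            raise AssertionError("confidence interval must contain the point estimate")


def build_analysis_frame(
    summaries: pd.DataFrame, covariates: pd.DataFrame, category: str
) -> pd.DataFrame:
    """Pivot participant-wave summaries to one row per participant with
    baseline/followup outcome columns, merged with covariates."""
    wide = summaries.pivot_table(
        index="participant_id", columns="wave", values=category, aggfunc="first"
    ).rename(columns={"baseline": "baseline_y", "followup": "followup_y"})
    cov_cols = [
        "participant_id",
        "household_id",
        "group",
        "housing_group",
        *BASE_COVARIATES,
    ]
    extra = [c for c in ("working_studying",) if c in covariates.columns]
    frame = wide.reset_index().merge(covariates[cov_cols + extra], on="participant_id", how="inner")
    return frame


def _formula(frame: pd.DataFrame, include_housing: bool) -> str:
    terms = ["baseline_y", "group"]
    for cov in BASE_COVARIATES:
        if frame[cov].nunique() > 1:
            terms.append(cov)
    if include_housing and frame["housing_group"].nunique() > 1:
        terms.append("housing_group")
    return "followup_y ~ " + " + ".join(terms)


def fit_change_model(
    frame: pd.DataFrame,
    *,
    outcome: str = "",
    stratum: str = "all",
    include_housing: bool = True,
) -> EffectEstimate:
    """Mixed model of follow-up on baseline with household random intercept.

    ``frame`` is the output of :func:`build_analysis_frame`, complete
    cases only (rows with a missing wave are dropped here).
    """
    data = frame.dropna(subset=["baseline_y", "followup_y"]).copy()
    if data["household_id"].nunique() < 2:
        raise ValueError("need at least 2 households to fit a household-clustered model")
    if data["group"].nunique() < 2:
        raise ValueError("need both intervention and control participants")
    formula = _formula(data, include_housing)

    model_kind = "mixed"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data, groups=data["household_id"]).fit(reml=True)
            coef = fit.fe_params[GROUP_TERM]
            se = fit.bse_fe[GROUP_TERM]
        resid = np.asarray(fit.resid)
        if not np.isfinite(se) or se <= 0:
            raise np.linalg.LinAlgError("degenerate group s.e.")
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed model failed (%s); falling back to OLS", exc)
        fit = smf.ols(formula, data).fit()
        coef = fit.params[GROUP_TERM]
        se = fit.bse[GROUP_TERM]
        resid = np.asarray(fit.resid)
        model_kind = "ols_fallback"

    z = coef / se
    p = 2 * st.norm.sf(abs(z))
    diag = _residual_diagnostics(resid)
    return EffectEstimate(
        outcome=outcome,
        stratum=stratum,
        n=len(data),
        difference=float(coef),
        ci_low=float(coef - 1.959963984540054 * se),
        ci_high=float(coef + 1.959963984540054 * se),
        p_value=float(p),
        model=model_kind,
        diagnostics=diag,
    )


def _residual_diagnostics(resid: np.ndarray) -> dict:
    """Normality summary for the model residuals (QQ correlation + Shapiro p)."""
    resid = resid[np.isfinite(resid)]
    if len(resid) < 8:
        return {}
    qq_theoretical = st.norm.ppf((np.arange(1, len(resid) + 1) - 0.5) / len(resid))
    qq_corr = float(np.corrcoef(np.sort(resid), qq_theoretical)[0, 1])
    sh_p = float(st.shapiro(resid[:5000]).pvalue)
    return {"qq_correlation": qq_corr, "shapiro_p": sh_p}


def stratified_effects(
    summaries: pd.DataFrame, covariates: pd.DataFrame, category: str
) -> list[EffectEstimate]:
    """Overall estimate plus one per housing group (housing dropped from the
    stratified covariate set). Single-group strata are skipped with a warning."""
    frame = build_analysis_frame(summaries, covariates, category)
    out = [fit_change_model(frame, outcome=category, stratum="all", include_housing=True)]
    for hg, sub in frame.groupby("housing_group", sort=True):
        if sub["group"].nunique() < 2 or sub["household_id"].nunique() < 2:
            logger.warning("stratum %s lacks both groups or enough households; skipped", hg)
            continue
        out.append(fit_change_model(sub, outcome=category, stratum=str(hg), include_housing=False))
    return out


def weekday_weekend(
    profiles: pd.DataFrame, covariates: pd.DataFrame, category: str
) -> dict[str, EffectEstimate]:
    """Fit the change model separately on weekday-only and weekend-only
    summaries. Participants without days in a subset drop out of it."""
    from modeshift.aggregate import ensure_profile_columns, participant_wave_summary

    profiles = ensure_profile_columns(profiles)
    results: dict[str, EffectEstimate] = {}
    for name, mask in (
        ("weekday", profiles["day_of_week"] < 5),
        ("weekend", profiles["day_of_week"] >= 5),
    ):
        sub = profiles[mask]
        if sub.empty or sub["wave"].nunique() < 2:
            raise ValueError(f"no usable {name} days in both waves")
        dropped = profiles["participant_id"].nunique() - sub["participant_id"].nunique()
        if dropped:
            logger.info("%d participants contribute no %s days", dropped, name)
        summaries = participant_wave_summary(sub, categories=(category,), method="adjusted")
        frame = build_analysis_frame(summaries, covariates, category)
        results[name] = fit_change_model(frame, outcome=f"{category}_{name}")
    return results


def impute_missing_followup(
    frame: pd.DataFrame,
    *,
    outcome: str = "",
    m: int = 40,
    seed: int = 0,
    include_housing: bool = True,
) -> EffectEstimate:
    """Multiply impute missing follow-up outcomes and pool by Rubin's rules.

    Imputation model: Bayesian linear regression of the follow-up outcome
    on baseline outcome, group and the covariates (proper imputation with
    parameter draws). Missingness is only allowed in ``followup_y``.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    if frame["baseline_y"].isna().any():
        raise ValueError("imputation supports missing follow-up outcomes only")
    rng = np.random.default_rng(seed)
    formula = _formula(frame, include_housing)

    rhs = formula.split("~", 1)[1]
    X_full = dmatrix(rhs, frame, return_type="dataframe").to_numpy()
    observed = frame["followup_y"].notna().to_numpy()
    mis = frame[~observed]
    X_obs = X_full[observed]
    X_mis = X_full[~observed]
    y_obs = frame.loc[observed, "followup_y"].to_numpy()
    n, k = X_obs.shape
    XtX_inv = np.linalg.inv(X_obs.T @ X_obs)
    beta_hat = XtX_inv @ X_obs.T @ y_obs
    resid = y_obs - X_obs @ beta_hat
    sigma2_hat = float(resid @ resid) / (n - k)

    estimates, variances = [], []
    chol = np.linalg.cholesky(XtX_inv)
    for _ in range(m):
        completed = frame.copy()
        if len(mis):
            sigma2_star = sigma2_hat * (n - k) / rng.chisquare(n - k)
            beta_star = beta_hat + np.sqrt(sigma2_star) * chol @ rng.standard_normal(k)
            completed.loc[completed["followup_y"].isna(), "followup_y"] = (
                X_mis @ beta_star + rng.normal(0, np.sqrt(sigma2_star), len(mis))
            )
        est = fit_change_model(completed, outcome=outcome, include_housing=include_housing)
        estimates.append(est.difference)
        variances.append(((est.ci_high - est.ci_low) / (2 * 1.959963984540054)) ** 2)

    qbar = float(np.mean(estimates))
    W = float(np.mean(variances))
    B = float(np.var(estimates, ddof=1))
    T = W + (1 + 1 / m) * B
    se = np.sqrt(T)
    if B > 0:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        tcrit = st.t.ppf(0.975, df)
        p = 2 * st.t.sf(abs(qbar / se), df)
    else:  # nothing was missing: pooled result equals the complete-case fit
        tcrit = 1.959963984540054
        p = 2 * st.norm.sf(abs(qbar / se))
    return EffectEstimate(
        outcome=outcome,
        stratum="all",
        n=len(frame),
        difference=qbar,
        ci_low=qbar - tcrit * se,
        ci_high=qbar + tcrit * se,
        p_value=float(p),
        model=f"mi_{m}",
        diagnostics={"between_var": B, "within_var": W},
    )


def effects_table(estimates: list[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": e.outcome,
                "stratum": e.stratum,
                "n": e.n,
                "difference": e.difference,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p_value": e.p_value,
                "model": e.model,
            }
            for e in estimates
        ]
    )
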