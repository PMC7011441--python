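"""Stage-by-stage orchestration of the full analysis chain.

Epoch fidelity exercises every stage (sensor emulation through change
models); day fidelity bypasses the sensor chain for statistical work at
full cohort size. ``CURRENT_STAGE`` is module state so failures can be
attributed to a stage by the caller.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from modeshift import aggregate, models, reporting, scores
from modeshift.config import CATEGORIES, SimConfig
from modeshift.mode_classifier import classify, smooth_labels
from modeshift.sensor_ingest import day_validity_table, filter_valid_days, fuse_epochs
from modeshift.underground_gaps import classify_underground, find_gaps
from modeshift.world import (
    emulate_sensors,
    generate_city,
    generate_cohort,
    generate_day_level,
    generate_diaries,
)
from modeshift.world.perception import generate_perception_responses

logger = logging.getLogger(__name__)

CURRENT_STAGE = "init"


def _stage(name: str) -> None:
    global CURRENT_STAGE
    CURRENT_STAGE = name
    logger.info("stage: %s", name)


def run(config: SimConfig, out: Path) -> dict:
    rng = np.random.default_rng(config.seed)
    result: dict = {}

    _stage("simulate")
    city = generate_city(config.seed) if config.fidelity == "epoch" else None
    cohort = generate_cohort(city, config, rng=rng)
    cohort.to_csv(out / "cohort.csv", index=False)

    _stage("covariates")
    covariates = scores.encode_covariates(cohort)

    if config.fidelity == "epoch":
        profiles, validity_b, validity_f = _epoch_chain(city, cohort, config, rng, out)
        _stage("exposures")
        from modeshift.built_env import ExposureEngine

        exposures = ExposureEngine(city).cohort_exposures(cohort)
        exposures.to_csv(out / "exposures.csv", index=False)
    else:
        _stage("day_level")
        profiles = generate_day_level(cohort, config, rng=rng)
        profiles = aggregate.ensure_profile_columns(profiles)
        validity_b = validity_f = None
        exposures = None

    profiles.to_csv(out / "day_profiles.csv", index=False)

    _stage("perceptions")
    resp_b = generate_perception_responses(cohort, "baseline", rng=rng)
    resp_f = generate_perception_responses(cohort, "followup", rng=rng)
    try:
        weights = scores.fit_perception_factors(resp_b)
        sc = pd.concat(
            [
                scores.score_perceptions(resp_b, weights).assign(wave="baseline"),
                scores.score_perceptions(resp_f, weights).assign(wave="followup"),
            ]
        )
        sc.index.name = "participant_id"
        sc.reset_index().to_csv(out / "perception_scores.csv", index=False)
        if exposures is not None:
            exposures = exposures.merge(
                sc.reset_index(), on=["participant_id", "wave"], how="left"
            )
    except ValueError as exc:
        logger.warning("perception factors skipped: %s", exc)

    _stage("aggregate")
    method = "adjusted" if config.fidelity == "epoch" else "mean"
    summaries = aggregate.participant_wave_summary(profiles, method=method)
    summaries.to_csv(out / "summaries.csv", index=False)

    _stage("models")
    all_effects = []
    for cat in (*CATEGORIES, "active_travel", "total_gps_min"):
        try:
            all_effects.extend(models.stratified_effects(summaries, covariates, cat))
        except ValueError as exc:
            logger.warning("model for %s skipped: %s", cat, exc)
    effects = models.effects_table(all_effects)
    effects.to_csv(out / "effects.csv", index=False)
    result["effects"] = len(effects)

    _stage("tables")
    reporting.table1(summaries, covariates).to_csv(out / "table1.csv", index=False)
    if exposures is not None:
        reporting.table2(exposures, covariates).to_csv(out / "table2.csv", index=False)
    if validity_b is not None:
        flow = reporting.cohort_flow(validity_b, validity_f, cohort)
        pd.DataFrame([flow.as_dict()]).to_csv(out / "cohort_flow.csv", index=False)

    _stage("done")
    return result


def _epoch_chain(city, cohort, config, rng, out: Path):
    _stage("diaries")
    episodes = generate_diaries(cohort, city, config, rng=rng)
    _stage("sensors")
    streams = emulate_sensors(episodes, config, rng=rng)
    streams.fixes.to_csv(out / "gps_fixes.csv", index=False)
    streams.accel.to_csv(out / "accel_epochs.csv", index=False)

    _stage("fuse_classify")
    profile_rows, validity_rows, all_gaps = [], [], []
    for (pid, wave), acc in streams.accel.groupby(["participant_id", "wave"]):
        fx = streams.fixes[
            (streams.fixes["participant_id"] == pid) & (streams.fixes["wave"] == wave)
        ]
        rec = fuse_epochs(fx, acc)
        validity = day_validity_table(
            rec,
            participant_id=pid,
            wave=wave,
            nonwear_min=config.nonwear_min,
            valid_day_min=config.valid_day_min,
        )
        validity_rows.append(validity)
        rec = filter_valid_days(rec, validity)
        if rec.empty:
            continue
        labels = classify(rec, "rule", rail_lines=city.rail_lines)
        labels = smooth_labels(labels)
        gaps = find_gaps(rec, min_gap_s=config.min_gap_s, participant_id=pid, wave=wave)
        gaps = classify_underground(
            gaps,
            city.underground_stations,
            mode=config.gap_endpoint_mode,
            radius_m=config.station_radius_m,
            min_duration_s=config.min_gap_s,
            max_duration_s=config.max_gap_s,
        )
        all_gaps.extend(gaps)
        prof = aggregate.summarise_days(labels, gaps, validity, participant_id=pid, wave=wave)
        if not prof.empty:
            profile_rows.append(prof)

    from modeshift.underground_gaps import gaps_table

    gaps_table(all_gaps).to_csv(out / "signal_gaps.csv", index=False)
    validity_all = pd.concat(validity_rows, ignore_index=True)
    validity_b = validity_all[validity_all["wave"] == "baseline"]
    validity_f = validity_all[validity_all["wave"] == "followup"]
    validity_all.to_csv(out / "day_validity.csv", index=False)
    profiles = pd.concat(profile_rows, ignore_index=True)
    return profiles, validity_b, validity_f
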