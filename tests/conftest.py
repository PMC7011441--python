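from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from modeshift.config import SimConfig
from modeshift.world import emulate_sensors, generate_city, generate_cohort, generate_diaries


@pytest.fixture(scope="session")
def city():
    return generate_city(seed=7, extent_m=2000.0, block_m=200.0, n_parks=2, n_underground=4)


@pytest.fixture(scope="session")
def epoch_config():
    return SimConfig(
        seed=11,
        n_participants=6,
        n_households=4,
        fidelity="epoch",
        wear_days=2,
        true_effects={},
    )


@pytest.fixture(scope="session")
def epoch_cohort(city, epoch_config):
    rng = np.random.default_rng(epoch_config.seed)
    return generate_cohort(city, epoch_config, rng=rng)


@pytest.fixture(scope="session")
def diary_episodes(city, epoch_config, epoch_cohort):
    rng = np.random.default_rng(epoch_config.seed + 1)
    return generate_diaries(epoch_cohort, city, epoch_config, rng=rng)


@pytest.fixture(scope="session")
def sensor_streams(diary_episodes, epoch_config):
    rng = np.random.default_rng(epoch_config.seed + 2)
    return emulate_sensors(diary_episodes, epoch_config, rng=rng)


@pytest.fixture(scope="session")
def fused_one(sensor_streams):
    """Fused records for one participant-wave (first participant, baseline)."""
    from modeshift.sensor_ingest import fuse_epochs

    fixes, accel, truth = sensor_streams
    pid = accel["participant_id"].iloc[0]
    fx = fixes[(fixes["participant_id"] == pid) & (fixes["wave"] == "baseline")]
    ac = accel[(accel["participant_id"] == pid) & (accel["wave"] == "baseline")]
    tr = truth[(truth["participant_id"] == pid) & (truth["wave"] == "baseline")]
    return fuse_epochs(fx, ac), tr


def make_day_cohort(n=60, nh=40, seed=0, **cfg_kwargs) -> tuple[pd.DataFrame, SimConfig]:
    cfg = SimConfig(seed=seed, n_participants=n, n_households=nh, **cfg_kwargs)
    rng = np.random.default_rng(seed)
    return generate_cohort(None, cfg, rng=rng), cfg


ZERO_NOISE_COUNTS = {
    "walking": (600.0, 0.0, 0.0),
    "cycling": (350.0, 0.0, 0.0),
    "vehicle": (60.0, 0.0, 0.0),
    "overground": (60.0, 0.0, 0.0),
    "underground": (60.0, 0.0, 0.0),
    "stationary_in": (25.0, 0.0, 0.0),
    "stationary_out": (45.0, 0.0, 0.0),
}


@pytest.fixture(scope="session")
def zero_noise_epochs(city):
    """Fused epochs + features + truth from a noiseless sensor run."""
    from modeshift.mode_classifier import extract_features
    from modeshift.sensor_ingest import fuse_epochs

    cfg = SimConfig(
        seed=64,
        n_participants=3,
        n_households=3,
        fidelity="epoch",
        wear_days=1,
        gps_noise_sd_m=0.0,
        indoor_dropout_prob=1.0,
        count_params=ZERO_NOISE_COUNTS,
    )
    cohort = generate_cohort(city, cfg, rng=np.random.default_rng(64))
    eps = generate_diaries(cohort, city, cfg, rng=np.random.default_rng(65))
    streams = emulate_sensors(eps, cfg, rng=np.random.default_rng(66))
    frames = []
    for (pid, wave), acc in streams.accel.groupby(["participant_id", "wave"]):
        fx = streams.fixes[
            (streams.fixes["participant_id"] == pid) & (streams.fixes["wave"] == wave)
        ]
        rec = fuse_epochs(fx, acc)
        feats = extract_features(rec, rail_lines=city.rail_lines)
        tr = streams.truth[
            (streams.truth["participant_id"] == pid) & (streams.truth["wave"] == wave)
        ]
        frames.append(feats.merge(tr[["timestamp", "true_mode"]], on="timestamp", how="inner"))
    data = pd.concat(frames, ignore_index=True)
    data["true5"] = data["true_mode"].replace(
        {"stationary_in": "stationary", "stationary_out": "stationary", "underground": "stationary"}
    )
    return data
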