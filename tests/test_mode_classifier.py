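import numpy as np
import pandas as pd
import pytest

from modeshift.config import SimConfig
from modeshift.mode_classifier import (
    FEATURE_COLUMNS,
    RuleThresholds,
    classify,
    extract_features,
    rule_classify,
    smooth_labels,
    train_model,
)
from modeshift.sensor_ingest import fuse_epochs
from modeshift.world import emulate_sensors, generate_cohort, generate_diaries


def _features_row(**kw):
    base = {
        "timestamp": pd.Timestamp("2014-05-05 09:00:00"),
        "speed_median": 0.0,
        "speed_p95": 0.0,
        "accel": 0.0,
        "counts": 0.0,
        "counts_window_mean": 0.0,
        "rail_dist_m": np.inf,
        "fix_fraction": 1.0,
    }
    base.update(kw)
    return pd.DataFrame([base])


class TestRuleClassify:
    def test_walking_band_with_counts(self):
        out = rule_classify(_features_row(speed_median=1.2, counts_window_mean=500))
        assert out["mode"].iloc[0] == "walking"

    def test_fast_near_rail_is_overground(self):
        out = rule_classify(_features_row(speed_median=15.0, rail_dist_m=40.0))
        assert out["mode"].iloc[0] == "overground"

    def test_fast_off_rail_is_vehicle(self):
        out = rule_classify(_features_row(speed_median=15.0, rail_dist_m=400.0))
        assert out["mode"].iloc[0] == "vehicle"

    def test_zero_speed_is_stationary(self):
        out = rule_classify(_features_row(speed_median=0.0, counts_window_mean=500))
        assert out["mode"].iloc[0] == "stationary"

    def test_mid_band_low_counts_is_vehicle(self):
        out = rule_classify(_features_row(speed_median=4.0, counts_window_mean=50))
        assert out["mode"].iloc[0] == "vehicle"

    def test_mid_band_high_counts_is_cycling(self):
        out = rule_classify(_features_row(speed_median=4.0, counts_window_mean=400))
        assert out["mode"].iloc[0] == "cycling"


def _constant_speed_records(v_ms=1.4, n=60, counts=600.0):
    ts = pd.date_range("2014-05-05 09:00:00", periods=n, freq="10s")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "counts": counts,
            "x": np.arange(n) * v_ms * 10,
            "y": 0.0,
            "has_fix": True,
            "speed": [np.nan] + [v_ms] * (n - 1),
            "worn": True,
        }
    )


class TestExtractFeatures:
    def test_constant_track_median_speed(self):
        feats = extract_features(_constant_speed_records(1.4))
        assert feats["speed_median"].iloc[10] == pytest.approx(1.4)

    def test_one_row_per_epoch_with_window_fix(self):
        rec = _constant_speed_records(n=30)
        feats = extract_features(rec)
        assert len(feats) == 30

    def test_no_fix_epochs_excluded(self):
        rec = _constant_speed_records(n=30)
        rec.loc[10:, ["has_fix"]] = False
        rec.loc[10:, "x"] = np.nan
        feats = extract_features(rec, window_s=60)
        # epochs far from any fix have no feature row
        assert len(feats) < 30
        assert len(feats) >= 10

    def test_window_must_be_multiple_of_10(self):
        with pytest.raises(ValueError):
            extract_features(_constant_speed_records(), window_s=25)


@pytest.fixture(scope="module")
def labelled_epochs(city):
    """Fused epochs + ground-truth labels from a small synthetic cohort."""
    cfg = SimConfig(seed=33, n_participants=4, n_households=3, fidelity="epoch", wear_days=1)
    cohort = generate_cohort(city, cfg, rng=np.random.default_rng(33))
    eps = generate_diaries(cohort, city, cfg, rng=np.random.default_rng(34))
    streams = emulate_sensors(eps, cfg, rng=np.random.default_rng(35))
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
        merged = feats.merge(tr[["timestamp", "true_mode"]], on="timestamp", how="inner")
        frames.append(merged)
    data = pd.concat(frames, ignore_index=True)
    data["true5"] = data["true_mode"].replace(
        {"stationary_in": "stationary", "stationary_out": "stationary", "underground": "stationary"}
    )
    return data


class TestTrainModel:
    def test_synthetic_training_accuracy(self, labelled_epochs):
        art = train_model(labelled_epochs, labelled_epochs["true5"], seed=0, n_trees=150)
        assert art.report.attrs["holdout_accuracy"] >= 0.9

    def test_permuted_labels_give_chance(self, labelled_epochs):
        rng = np.random.default_rng(1)
        # balanced subsample over the 5 classes, then permute
        sub = labelled_epochs.groupby("true5").head(400)
        y = rng.permutation(sub["true5"].to_numpy())
        art = train_model(sub, y, seed=0, n_trees=50)
        k = sub["true5"].nunique()
        assert art.report.attrs["holdout_accuracy"] < 1.5 / k + 0.15

    def test_single_class_rejected(self, labelled_epochs):
        sub = labelled_epochs[labelled_epochs["true5"] == "stationary"]
        with pytest.raises(ValueError, match="2 classes"):
            train_model(sub, sub["true5"], seed=0)

    def test_deterministic_given_seed(self, labelled_epochs):
        a = train_model(labelled_epochs, labelled_epochs["true5"], seed=3, n_trees=60)
        b = train_model(labelled_epochs, labelled_epochs["true5"], seed=3, n_trees=60)
        X = labelled_epochs[list(FEATURE_COLUMNS)].to_numpy()
        X = np.where(np.isinf(X), 1e6, X)
        assert (a.model.predict(X) == b.model.predict(X)).all()

    def test_artifact_roundtrip(self, labelled_epochs, tmp_path):
        from modeshift.mode_classifier import ModelArtifact

        art = train_model(labelled_epochs, labelled_epochs["true5"], seed=0, n_trees=30)
        art.save(tmp_path / "model.pkl")
        back = ModelArtifact.load(tmp_path / "model.pkl")
        assert back.classes == art.classes


class TestClassify:
    def test_empty_input(self):
        out = classify(pd.DataFrame(columns=["timestamp", "worn"]), "rule")
        assert out.empty

    def test_pure_walking_day_mostly_walking(self):
        rec = _constant_speed_records(v_ms=1.4, n=360)
        labels = classify(rec, "rule")
        assert (labels["mode"] == "walking").mean() >= 0.9

    def test_no_gps_epochs_stationary_when_worn(self):
        rec = _constant_speed_records(n=30)
        rec["has_fix"] = False
        rec["x"] = np.nan
        rec["speed"] = np.nan
        labels = classify(rec, "rule")
        assert (labels["mode"] == "stationary").all()

    def test_label_completeness(self, fused_one):
        rec, _ = fused_one
        labels = classify(rec, "rule")
        assert len(labels) == rec["worn"].sum()

    def test_untrained_classifier_name_rejected(self, fused_one):
        rec, _ = fused_one
        with pytest.raises(ValueError):
            classify(rec, "nonsense")


class TestRuleModelConsistency:
    def test_rule_vs_model_agreement_on_noiseless_data(self, zero_noise_epochs):
        # oracle equivalence: on zero-noise epochs the trained model and the
        # deterministic rule cascade agree on >= 95% of labels
        from modeshift.mode_classifier import rule_classify

        art = train_model(zero_noise_epochs, zero_noise_epochs["true5"], seed=0, n_trees=150)
        X = zero_noise_epochs[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        X = np.where(np.isinf(X), 1e6, X)
        model_pred = art.model.predict(X)
        rule_pred = rule_classify(zero_noise_epochs)["mode"].to_numpy()
        assert (model_pred == rule_pred).mean() >= 0.95

    def test_confusion_structure_speed_adjacency(self, labelled_epochs):
        # walking<->cycling confusion should not be smaller than
        # walking<->vehicle confusion (adjacent vs distant speed bands)
        art = train_model(labelled_epochs, labelled_epochs["true5"], seed=1, n_trees=150)
        X = labelled_epochs[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        X = np.where(np.isinf(X), 1e6, X)
        pred = art.model.predict(X)
        truth = labelled_epochs["true5"].to_numpy()
        walk = truth == "walking"
        wc = ((pred == "cycling") & walk).sum() + ((pred == "walking") & (truth == "cycling")).sum()
        wv = ((pred == "vehicle") & walk).sum() + ((pred == "walking") & (truth == "vehicle")).sum()
        assert wc >= wv


class TestSmoothLabels:
    def _labels(self, modes):
        return pd.DataFrame(
            {
                "timestamp": pd.date_range("2014-05-05", periods=len(modes), freq="10s"),
                "mode": modes,
                "source": "rule",
            }
        )

    def test_short_run_absorbed(self):
        out = smooth_labels(self._labels(["W", "W", "V", "W", "W"]), min_run_s=30)
        assert list(out["mode"]) == ["W"] * 5

    def test_long_runs_unchanged(self):
        modes = ["W"] * 5 + ["V"] * 5
        out = smooth_labels(self._labels(modes), min_run_s=30)
        assert list(out["mode"]) == modes

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            modes = list(rng.choice(["W", "V", "C"], size=12))
            once = smooth_labels(self._labels(modes), min_run_s=30)
            twice = smooth_labels(once, min_run_s=30)
            assert list(once["mode"]) == list(twice["mode"])

    def test_tie_goes_to_earlier_neighbour(self):
        # V run of 2 between equal-length W and C runs -> absorbed into earlier (W)
        out = smooth_labels(self._labels(["W", "W", "W", "V", "V", "C", "C", "C"]), min_run_s=30)
        assert list(out["mode"]) == ["W"] * 5 + ["C"] * 3

    def test_smoothed_source_marked(self):
        out = smooth_labels(self._labels(["W", "W", "W", "V", "W", "W"]), min_run_s=30)
        assert (out.loc[out["mode"] != "W", "source"] == "smoothed").sum() == 0
        assert (out["source"] == "smoothed").sum() == 1
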