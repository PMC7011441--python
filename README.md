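# modeshift

A tested, reusable pipeline for evaluating the effect of moving into a
redesigned neighbourhood on objectively measured travel behaviour — a
natural-experiment design with two measurement waves.

The pipeline runs from raw (synthetic) 10-second accelerometer counts and
GPS fixes, through travel-mode classification and underground signal-gap
inference, to household-clustered multilevel estimates of the
between-group difference in change of daily minutes per motion category
(walking, cycling, motorised vehicle, overground train, underground
train, stationary). A vector "city" model supplies built-environment
exposures: walkability (land-use-mix + residential-density +
street-connectivity z-sum in a 1-km network buffer), network distance to
the nearest park entrance, and nearest-point public-transport
accessibility scores.

Because no raw study data are public, a first-class synthetic-data module
generates seeded cohorts with known ground truth at two fidelity levels:

* **epoch** — full sensor emulation (travel diaries routed on the street
  network, 10-s GPS fixes with dropout, 10-s count epochs), used to
  exercise the ingest/classification/gap stages;
* **day** — direct draws of per-day category minutes from a three-level
  (household / person / day) model with configurable true intervention
  effects, used for statistical parameter recovery at full cohort size.

## Command line

```bash
modeshift simulate  --config cfg.yaml --seed 1 --out outdir   # raw streams / day table
modeshift run       --config cfg.yaml --seed 1 --out outdir   # full pipeline + tables
modeshift exposures --city outdir/city --addresses addr.csv --out exposures.csv
modeshift classify  --records fused.csv --rule --out labels.csv
modeshift aggregate --profiles day_profiles.csv --out summaries.csv
modeshift model     --summaries summaries.csv --cohort cohort.csv --out effects.csv
```

`cfg.yaml` holds `SimConfig` keys (see `modeshift/config.py`), e.g.:

```yaml
fidelity: day
n_participants: 578
n_households: 400
wear_days: 4
true_effects:
  vehicle: -8.3
  underground: 3.9
```

## Package layout

| module | role |
| --- | --- |
| `modeshift.world` | synthetic city, cohort, diaries, sensor streams, day-level generator |
| `modeshift.sensor_ingest` | GPX/delimited GPS readers, 10-s epoch fusion, wear time, valid days |
| `modeshift.mode_classifier` | windowed features, rule cascade (oracle), gradient-boosted model, label smoothing |
| `modeshift.underground_gaps` | GPS signal-loss gaps and the 2 min–2 h / 200 m underground rule |
| `modeshift.built_env` | 1-km network buffers, walkability components, park distance, PTAL assignment |
| `modeshift.scores` | 2-factor EFA perception scores (promax, regression scoring), covariate encoding |
| `modeshift.aggregate` | daily category minutes, residual-adjusted per-participant averages |
| `modeshift.models` | change models, stratified/weekday-weekend/multiple-imputation analyses |
| `modeshift.reporting` | cohort flow, baseline/exposure-change/effect tables, pipeline orchestration |
| `modeshift.recovery` | replicated-synthetic-cohort parameter-recovery harness |

Notes on scope: bus and car travel are a single "vehicle" class (they are
not separable from speed/counts alone); PTAL scores are assigned from the
nearest sample point, never recomputed; no route inference inside
underground gaps.
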