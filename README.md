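# gaitrecover

Probabilistic gait-recovery monitoring from wearable kinematics.

`gaitrecover` implements an end-to-end analysis pipeline for monitoring
functional recovery after total knee arthroplasty (TKA) from IMU-derived
joint-angle time series:

1. **`synthetic_cohort`** — seeded generator of synthetic cohorts (joint-angle
   channels with planted gait events, per-subject latent severity, KOOS-ADL
   trajectories stochastically coupled to gait deviation). The original study
   data is GDPR-restricted, so every downstream stage is developed and tested
   against this generator's planted ground truth.
2. **`segmentation`** — walking step detection from anterior-posterior
   acceleration peaks, left/right assignment from medio-lateral acceleration,
   stair-stride detection from tibia-acceleration extrema, zero-phase 6 Hz
   low-pass filtering, middle-stride extraction and time normalization to
   101 points (0–100 % of stride).
3. **`feature_construction`** — views = 9 input channels plus fused series
   (ratio / difference / sum / product of channel pairs) pruned at a 0.99
   Pearson-correlation redundancy threshold; a fixed 15-statistic bank per
   view (moments, extrema, RMS, Fourier coefficient magnitudes 1–5, linear
   trend); per subject-activity-timepoint averaging (both legs for controls,
   affected side only for patients).
4. **`classifier`** — standard scaling from training rows only,
   L1-regularised logistic regression (LIBLINEAR, max 100 iterations), C
   tuned over 10 log-spaced values in [0.01, 1] by stratified 5-fold CV on
   mean AUC, leave-one-subject-out evaluation with per-fold refitting of the
   scaler and the fusion-view list.
5. **`monitoring`** — deployment of a trained model across post-operative
   timepoints into per-patient probability trajectories, 6-week→12-month
   change-score Spearman correlation against KOOS-ADL, and per-subject
   longitudinal correlations banded weak/fair/moderate/strong at
   |rho| = 0.25/0.5/0.75.
6. **`cli_io`** — YAML configuration, plain-text artifacts (CSV/JSON), a
   deterministic end-to-end pipeline with a checksummed run manifest, and the
   `gaitrecover` command-line interface.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite:
segmentation oracles against planted events, scaling/closed-form contracts,
a label-permutation leakage null, strong-signal recovery, trajectory trend
recovery, correlation machinery against brute-force rank computation, and
fusion-pruning soundness. The full suite takes a few minutes on one CPU
(five complete pipeline runs are executed twice over).

## Command line

```bash
# everything in one go: simulate -> segment -> features -> train -> monitor
gaitrecover run-all --seed 42 --out-dir out/

# or stage by stage
gaitrecover simulate --n-controls 20 --n-patients 19 --effect-size 2 \
    --coupling 0.9 --seed 42 --out-dir out/
gaitrecover segment --trials-csv out/trials.csv --out out/strides.csv
gaitrecover features --strides-csv out/strides.csv --cohort-csv out/cohort_meta.csv \
    --out out/features.csv --sidecar out/features.json
gaitrecover train --strides-csv out/strides.csv --cohort-csv out/cohort_meta.csv \
    --activity walk --train-timepoint w6 --seed 42 \
    --out-model out/model.json --loocv-out out/loocv.csv
gaitrecover monitor --model out/model.json --strides-csv out/strides.csv \
    --cohort-csv out/cohort_meta.csv --prom-csv out/proms.csv \
    --loocv-csv out/loocv.csv --out-dir out/monitoring
```

`run-all` on the default 39-subject cohort (three activities, two training
variants, six models) takes ~1–2 minutes on one CPU and writes a
`manifest.json` with the config hash, per-model LOOCV accuracies, file
checksums and collected warnings; re-running the same config reproduces
identical checksums.

## Layout

```
src/gaitrecover/
  synthetic_cohort.py    cohort/trial/PROM generator with planted ground truth
  segmentation.py        event detection, middle stride, 101-point normalization
  feature_construction.py  view fusion, pruning, feature bank, aggregation
  classifier.py          scaling, L1-LR tuning, LOOCV, probability prediction
  monitoring.py          trajectories, change scores, Spearman bands, heatmap
  cli_io.py              config, serialization, pipeline, CLI
tests/                   unit + property + acceptance suites
scripts/acceptance.py    acceptance report
```
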