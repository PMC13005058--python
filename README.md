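# turnsignal

Digital-biomarker analysis of naturalistic driving for early screening of
mild cognitive impairment (MCI). Driving engages attention, working memory,
processing speed and spatial orientation; subtle impairment shows up as
altered vehicle kinematics — especially rapid micro-adjustments of speed and
steering inside turning maneuvers. `turnsignal` turns raw in-vehicle sensor
streams (1 Hz GPS; 24 Hz accelerometer and gyroscope) into trip- and
turn-level multivariate time series, trains deep sequence classifiers under
three fusion paradigms, and aggregates trip-level predictions into an
interpretable participant risk score.

The package is aimed at researchers prototyping sensor-based cognitive
screening pipelines. Because real clinical driving cohorts are private, it
ships a synthetic cohort generator with a controllable, episodic impairment
signature, so every stage — cleaning rules included — is testable end to end.

## Pipeline

1. **Cleaning** — segment streams into trips at >60 s timestamp gaps,
   cross-check per-sensor trip counts, merge 24 Hz IMU channels onto the 1 Hz
   GPS timeline by block averaging, drop incomplete seconds and trips.
2. **Turn extraction** — project GPS to a local plane
   (x = R·λ·cos φ_ref, y = R·φ, R = 6371 km), threshold successive heading
   changes at 10° (0.174533 rad), discard zero-speed candidates, merge
   adjacent candidates to their median index, and cut ±15 s windows
   (31 steps × 10 channels) around each peak.
3. **Features** — 10 channels: speed, 3 linear accelerations, 3 angular
   velocities, and 3 derived angular accelerations (temporal gradients of the
   gyroscope); plus a 14-feature static mean/SD baseline.
4. **Tensors** — linear interpolation to fixed lengths: trips to
   N × 10 × 1200, concatenated turns to 310 (late fusion) or 1200 (early
   fusion, stacked to N × 20 × 1200).
5. **Models** — compact 1D-CNN (TinyFCN, Inception, ResNet-TSC), RNN
   (GRU/LSTM ± attention) and TCN families, plus dual-encoder late fusion
   with concatenation or a learned gate; implemented on a small numpy
   autodiff engine, trained with AdamW + cosine annealing + weighted
   cross-entropy.
6. **Evaluation** — participant-stratified 7-fold cross-validation (no
   driver on both sides of a fold), imbalance-aware metrics.
7. **Risk scoring** — per driver, the proportion of trips flagged impaired
   (in [0, 1]); thresholds at 10%/50% trade sensitivity against precision,
   with majority vote as the baseline it replaces.

## Worked example

```python
from turnsignal import (CohortConfig, DrivingClassifier, ModelSpec,
                        TrainConfig, build_datasets, generate_cohort)

cohort = generate_cohort(CohortConfig(          # 12 healthy + 7 MCI drivers
    trips_per_participant=(3, 5), trip_duration_s=(120, 240),
    turn_count_per_trip=(4, 8), effect_size=2.5, seed=1))
ds = build_datasets(cohort)                     # clean + extract + tensorize
clf = DrivingClassifier(ds.trip, ModelSpec("tiny_fcn"),
                        TrainConfig(epochs=20, batch_size=8, lr=3e-3,
                                    normalize=True))
res = clf.fit(k=7, seed=1)
print(res.summary())
print(res.risk_report(thresholds=(0.1, 0.5)).to_frame().head(4).to_string())
```

prints

```
Cross-validated driving-biomarker classifier
====================================================
model family:     tiny_fcn
input:            C=10, L=1200
folds:            7 (participant-stratified, k=7)
epochs/batch/lr:  20/8/0.003
normalize=True  class_weights=True  seed=1
----------------------------------------------------
accuracy           0.764
balanced_accuracy  0.730
auc                0.867
precision          0.602
recall             0.610
f1                 0.601
----------------------------------------------------
confusion (pooled): TP=19 FP=8 TN=37 FN=11
  participant_id  n_trips  n_flagged  risk_score  trip_accuracy  flag_0.1  flag_0.5
0            001        5          0         0.0            1.0     False     False
1            002        3          0         0.0            1.0     False     False
2            003        5          2         0.4            0.6      True     False
3            004        3          0         0.0            1.0     False     False
```

The cohort plants a 2.5× inflation of within-turn speed/yaw-rate fluctuation
on MCI trips; the summary shows the cross-validated recovery of that effect
(AUC 0.87 on this seed), and the risk table converts held-out trip
predictions into per-driver screening flags: at the sensitive 10% threshold a
single flagged trip is enough to recommend follow-up, at 50% only drivers
impaired on most trips are flagged.

The same pipeline is scriptable from the shell:

```sh
turnsignal simulate --config cohort.yaml --out raw/ --seed 1
turnsignal clean --in raw/ --out clean/
turnsignal extract-turns --in raw/ --out turns/
turnsignal run-experiment --experiment 1a --model TinyFCN --epochs 25 \
    --seed 1 --out results/
```

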