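# hometwin

A synthetic **home digital-twin mobility pipeline**: it simulates a wearable
home-monitoring study — 12 body-worn orientation sensors, an ultra-wideband
(UWB) tag localized by 5 wall anchors in a 5-room apartment, 19 scripted
activities of daily living — and reconstructs everything a real study would
report, end to end:

1. **Joint kinematics** — world-frame sensor quaternions (225 Hz) with
   arbitrary mounting are calibrated to anatomical segments from two static
   poses (TRIAD on the gravity readings), slerp-resampled to 100 Hz, and
   decomposed into anatomical joint angles: shoulder and trunk by the
   intrinsic Y–X′–Y″ sequence (plane of elevation, elevation, axial
   rotation), elbow/hip/knee/ankle by Z–X′–Y″ (flexion first).
2. **Indoor localization** — TDOA range differences
   Δᵢ = ‖p−aᵢ‖ − ‖p−a₁‖ at ~5 Hz are solved per frame by
   Levenberg–Marquardt least squares; the trajectory yields instantaneous
   speed (0.2 s displacement–time ratio), total distance, per-room occupancy
   time and per-room walking speed.
3. **Activity recognition** — 50 %-overlap sliding windows (0.1–2.0 s grid)
   carry mean/SD of each angle channel and of its first and second
   derivatives; KNN (k = 9, 1.3 s window) and a one-vs-rest RBF SVM are
   evaluated by leave-one-subject-out cross-validation.
4. **Mobility outcomes** — window labels merge into activity episodes;
   occurrence counts, accumulated durations, and range-of-motion maxima
   (shoulder plane of elevation/elevation, hip/knee flexion, ankle
   dorsi/plantarflexion) are compared between predicted and truth-labeled
   arms with paired t-tests, Benjamini–Hochberg FDR, 95 % CIs and Cohen's d.

Because every recording is generated from known parameters, each stage can be
held against exact ground truth — which is the point: the package is a test
bench for this class of wearable analytics, for biomechanists and methods
developers who want to know what such a pipeline recovers before trusting it
on human recordings.

## Worked example

```python
from hometwin.config import RunConfig
from hometwin.cohort import build_subject, angle_rmse_by_channel
from hometwin.synth import generate_layout

cfg = RunConfig(root_seed=1, n_subjects=1, duration_s=300.0, imu_noise_deg=0.0)
layout = generate_layout(1)
subject = build_subject(layout, cfg, "s01", 1, 1, 1)
print(f"worst-channel RMSE: {angle_rmse_by_channel(subject).max():.4f} deg")
```

prints `worst-channel RMSE: 0.0418 deg`: with noiseless sensing and randomly
mounted sensors, the calibration + decomposition chain reproduces the true
joint angles to hundredths of a degree. The numbered drivers under
`analysis/` run the full study (each accepts `--seed`, default 1, and writes
its tables under `results/`):

```text
01_simulate_home.py        layout + 10 subject schedules
02_joint_angle_recovery.py per-channel RMSE: 0.042 deg noiseless,
                           1.26 deg at 1 deg sensor noise, 0.000 deg after
                           re-drawing the mounting rotations
03_localization.py         median position error 0.032 m at 0.12 m ranging
                           noise; per-room speeds within ~3 % of configured
04_classification.py       LOSO KNN9 @ 1.3 s: 95.3 % over 9220 windows;
                           largest confusion 21.6 % lying_phone -> lying
                           (the designed near-identical pair)
05_mobility_summary.py     predicted-vs-measured episode counts, durations,
                           ROM maxima with paired t + FDR
06_stats_validation.py     paired-t type-I error 0.049 at alpha 0.05;
                           BH family null discovery rate 0.053
```

A `hometwin` CLI wraps the same stages for file-based runs
(`hometwin run --seed 1 --run-dir runs/demo --subjects 2 --duration 300`,
plus per-stage verbs `simulate`, `calibrate`, `angles`, `localize`,
`classify`, `summarize`, `report`, `export-bvh` — the latter writes a BVH
skeletal animation driven by the recovered angles and UWB trajectory).

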