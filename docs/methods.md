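# Methods

## The simulated study

The generator emulates a wearable home-monitoring protocol: a single-bedroom
apartment (12 m × 8 m, five rooms tiling the floor plan; interior walls
jittered ±0.3 m per seed), five UWB anchors on the exterior walls at 1.8 m,
and eleven points of interest (bed, sofa, desk, kitchen bench, mirror, …).
Ten synthetic subjects each perform a 10-minute recording covering 19
activity-of-daily-living classes.

**Schedules.** Sustained activities are drawn with realistic relative
frequencies (postural transitions and reaching recur tens of times per hour;
grooming and meals only a few times) and connected by a postural state
machine with three states — upright, seated, lying. Entering a seated or
lying activity inserts its natural transition (stand-to-sit, sit-to-lie, …),
and moving to a new point of interest requires standing up and walking
there; the two walking variants alternate ~65/35. Subjects preferentially
chain tasks within the current room (p = 0.65) as people do. Episode
boundaries snap to a 10 ms grid so sampled label streams conserve scheduled
dwell times exactly. The schedule enforces no other behavioral logic (no
diurnal structure, no rest-break convention beyond the `standing` class).

**Motion.** Real human kinematics are replaced by per-activity channel
archetypes: each of 33 joint-angle channels (trunk, 2 shoulders, 2 elbows,
2 hips, 2 knees, 2 ankles × 3 angles) follows a hold, sinusoid, ramp-hold,
pulse, or transition-spline waveform. Baselines and amplitudes are seeded
from representative task kinematics (hair combing elevates the shoulder to
~124°, sit-to-stand flexes the knee to ~92°, gait oscillates the ankle
±15.5° with the legs in antiphase, walking-while-phone slows the cadence and
pins the elbows at ~75°). Per-subject style adds Gaussian baseline shifts
(channel SDs 1–3°, globally scaled by 0.7) and ±6 % amplitude scaling; each
episode gets a random sinusoid phase. `lying` vs `lying_phone` are
**designed to be nearly identical** — they differ only in a small elbow
posture/oscillation buried in the subject variation — so the classifier
faces one genuinely confusable pair. Episode boundaries crossfade over
0.3 s (smoothstep partition of unity), and the proper-Euler second angles
(elevation/inclination) are kept ≥ 3° so decompositions stay well-posed.
Segment world orientations are composed through the kinematic chain with the
same Euler conventions the analysis uses to decompose, which makes the truth
exactly recoverable; the pelvis is the world-aligned root (no heading), so
trunk inclination is defined against the world vertical.

**Sensors.** Each of the 12 segments carries a sensor at a random fixed
mounting rotation. Sensor streams are the segment orientation composed with
the mounting, sampled at 225 Hz, perturbed by isotropic rotation-vector
noise whose total-angle SD is the configured value (default 0.3°, the scale
of a fused orientation output; an optional linear heading drift is off by
default — all sensors share one ideal world frame). Two static calibration
poses are emulated by their accelerometer gravity readings: an upright
N-pose (gravity along every segment's long axis) and a 90°-forward-flexed
pose — an idealization in which every segment pitches 90° about the same
horizontal axis, chosen so the two gravity directions are non-collinear for
every segment. The UWB tag rides at the body centroid (not a forearm, to
avoid modeling arm swing) and reports planar range differences to anchors
2–5 relative to anchor 1 at 5 Hz with Gaussian ranging noise (default
0.12 m, matching ~30 cm positioning accuracy).

## Reconstruction pipeline

Quaternion streams are hemisphere-canonicalized and slerp-resampled onto the
common 100 Hz grid spanning the streams' overlap. TRIAD calibration builds
the sensor-to-segment rotation from the two pose gravities (long axis from
pose 1, Gram–Schmidt second axis from pose 2, third by cross product);
gravities closer than 15° are rejected as degenerate. Joint rotations
R_parentᵀ·R_child are decomposed by the intrinsic sequences above. Two
singularities are handled explicitly: at elevation < 1° the plane of
elevation is indeterminate and carried forward from the last well-posed
sample (the axial angle absorbs the remainder); Z–X′–Y″ samples within 1° of
the ±90° gimbal are flagged and linearly interpolated. First/third Euler
channels are unwrapped, then all channels pass a zero-phase 2nd-order
Butterworth low-pass at 8 Hz. The cutoff matters: the first/third
proper-Euler angles amplify orientation noise by ~1/sin(second angle), and
at everyday arm elevations unfiltered 1° sensor noise would leave several
degrees of channel noise; at 8 Hz the filter attenuates that below 2° RMSE
while distorting sub-Hz movement content by < 0.1 %.

Localization solves each TDOA frame by Levenberg–Marquardt nonlinear least
squares warm-started at the previous solution (anchor centroid initially);
non-converged or high-residual (> 1 m RMS) frames are flagged and carried
forward. Positions are linearly resampled to 100 Hz and smoothed with a
zero-phase 0.5 Hz 2nd-order low-pass before any speed or distance is
derived — raw UWB jitter would otherwise inflate path length (a noisy
stationary tag keeps < 5 % of its spurious distance after smoothing). Speed
uses the trailing 0.2 s displacement–time ratio; per-room walking speed
averages only samples whose whole displacement window lies within walking,
so stationary time never leaks into the ratio. Room assignment is
point-in-polygon with a fixed room order breaking boundary ties, so per-room
occupancy minutes conserve the recording duration exactly.

Classification windows (50 % overlap, trailing partial window dropped) take
the modal activity and room label, an exact tie going to the earlier-starting
run. Features are the per-channel mean and SD of the angle and of its first
and second finite differences (×rate, ×rate²) — 6 per channel, 198 total.
Features are centered per feature and scaled **per feature type** (one
pooled scale for each of the six families): all channels share units, and
per-feature z-scoring would inflate low-variance channels until
between-subject style noise drowned large between-class angle differences
(we measured pure windows with a 47° elevation gap being misclassified under
per-feature scaling). The scaler is fit on training folds only. KNN uses
Euclidean distance with deterministic tie-breaks (equal distances → lower
training index; tied vote → the nearest neighbor holding a tied label); the
SVM is one-vs-rest RBF (C = 10, γ = "scale" — unreported in comparable
protocols, fixed in config). Evaluation is leave-one-subject-out with the
pooled confusion matrix over all folds.

Episodes merge consecutive same-label windows; with a positive gap tolerance
(default one window step, 0.65 s) a short foreign run whose time gap between
same-label flanks is within tolerance is bridged; episodes under 0.5 s are
discarded. Because a merged episode overreaches its true span by up to half
a window at each end, ROM extrema are taken on the episode trimmed by
window/2 + 0.2 s (plain truth episodes use the 0.2 s blend margin only).
Per-activity outcomes average episodes within subject first, then report
mean ± SD across subjects — matching the per-subject paired testing.
Statistics: two-sided paired t with Student-t 95 % CI; Cohen's d for paired
designs as mean(d)/SD(d) (a pooled-SD variant is available); BH step-up FDR
applied within each comparison table (one family per outcome); normality by
the one-sample KS statistic against estimated parameters with Lilliefors
p-values. Degenerate inputs (zero-variance differences, constant samples,
< 2 pairs) are flagged or rejected rather than silently passed.

## Defaults and the numbers behind them

| parameter | default | why |
|---|---|---|
| sensor rate | 225 Hz | wearable fused-orientation output rate |
| common rate | 100 Hz | analysis grid for angles and positions |
| UWB rate / noise | 5 Hz / 0.12 m | ranging that yields ~30 cm accuracy |
| sensor noise | 0.3° | fusion-grade orientation error |
| angle low-pass | 8 Hz | noise suppression, < 0.1 % signal distortion |
| position low-pass | 0.5 Hz | walking dynamics pass, UWB jitter does not |
| window / overlap | 1.3 s / 50 % | selected classifier operating point |
| KNN k | 9 | selected neighbor count |
| gap tolerance / min episode | 0.65 s / 0.5 s | one window step; sub-window episodes are artifacts |
| cohort | 10 × 600 s | study-scale default |

## What passing tests do and do not show

The generator produces separable-by-design classes with mild subject
variation, ideal synchronization, and no soft-tissue artifact, magnetometer
disturbance, NLOS multipath, or open-set activity. Passing therefore
demonstrates the **correctness of the inference chain** — calibration
absorbs arbitrary mounting exactly, decompositions invert, the localizer is
statistically efficient, cross-validation leaks nothing — not that these
accuracy levels transfer to human recordings. Two known divergences from
real data: (1) LOSO accuracy here (~95 %) exceeds what real cohorts yield,
by construction; the confusion *structure* (the lying pair dominating,
transitions bleeding into their flanking postures) is the realistic part.
(2) Short windows are not penalized: with parametric archetypes and small
noise, a 0.1 s window already carries near-fully discriminative posture
means, so accuracy does not rise with window length the way it does on real
recordings where short windows are noise-dominated.

Other limitations: straight-line walking paths ignore walls and furniture;
the pelvis never rotates in the world (no heading), so trunk axial rotation
is relative to a fixed frame; the two calibration poses are idealized (real
protocols cannot flex every segment by exactly 90°); transition archetypes
are kinematic sketches, not dynamically consistent sit-to-stand mechanics;
and the BVH export converts Y–X′–Y″ joints to Z–X′–Y″ channels, which is
ill-conditioned if a joint passes exactly through the ±90° gimbal of the
target sequence (clean of that in the default motions).
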