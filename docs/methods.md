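# Methods

`fatlat` analyses exercise-induced fatigue by embedding multimodal
wearable-sensor repetitions into a 2-D latent space with adversarial
autoencoders and quantifying how per-set latent clusters drift as a
participant approaches exhaustion. This note documents the models, the
synthetic data, the numerical choices and the limitations.

## Study design being modelled

Two groups perform four lower-body exercises (Squat, Lunge Left, Lunge
Right, Plank Jump-in) in sets of 10 repetitions. Group A (default 20
subjects) performs one set per exercise without fatigue and is used for
model training and validation under user-independent K-fold
cross-validation (default K = 4; every subject appears in exactly one
validation block). Group B (default 10 subjects) repeats sets until
exhaustion and is used only for fine-tuning and fatigue analysis — it
never contributes to standardization statistics or model selection.

Sensors: a balance board with four vertical load cells sampled at 30 Hz,
and three IMUs (hip and both distal forearms; 3-axis accelerometer +
gyroscope) at 60 Hz. Five sensor-combination variants are analysed:
DB0 board only (3 channels), DB1 board + hip IMU (9), DB2 board + all
three IMUs (21), DB3 hip IMU only (6), DB4 all three IMUs (18).

## Preprocessing

Fixed pipeline order, each stage pure:

1. **T-pose calibration.** Per session, a static window in which all body
   segments are assumed world-aligned. The minimal rotation aligning the
   mean accelerometer vector with the world vertical (magnitude g =
   9.80665 m/s²) maps sensor to world frame; yaw is unobservable from
   gravity and left unresolved. Windows shorter than 0.5 s or with gyro
   activity above 0.2 rad/s are rejected.
2. **Gravity removal and height normalization.** The constant gravity
   reaction is subtracted in the world frame and acceleration divided by
   participant height (units 1/s² per metre of stature).
3. **GRF/CoP derivation.** Total vertical force is the sum of the four
   corner cells, normalized by body mass (N/kg). Centre of pressure
   follows from the corner-force moments over the sensor rectangle
   (default 0.238 m × 0.433 m); the first-frame CoP is subtracted so every
   repetition starts at (0, 0). Unloaded stretches (flight phases; total
   force < 50 N) are tolerated up to 30% of frames, with CoP interpolated
   across them.
4. **Low-pass filtering.** 4th-order Butterworth at 15 Hz applied
   forward–backward (zero phase; effective gain 0.5 at the cutoff).
   Filtering happens at native rates before resampling. At the board's
   30 Hz the cutoff coincides with Nyquist, so board channels pass through
   unfiltered — the filter would be the identity over their band anyway.
5. **Segmentation** (for concatenated streams): a moving-average envelope
   of the gravity-free acceleration magnitude is thresholded (default
   0.3 m/s², 0.1 s window); bursts separated by less than 0.5 s merge, and
   bursts shorter than 0.5 s are dropped. Intervals are half-open, 0-based
   sample indices. The standard path receives pre-segmented repetitions.
6. **Resampling.** Each channel is cubic-spline interpolated onto 192
   uniformly spaced frames spanning its repetition window; endpoints are
   preserved exactly. 192 divides by 2³, matching the three pooling
   stages of the encoder (192 → 96 → 48 → 24).
7. **Standardization.** z-scoring with a scalar mean/SD per signal *type*
   (GRF, CoP, acceleration, angular velocity), pooled over all channels
   of the type and computed only from the Group-A training subjects of
   the current fold; the same statistics standardize validation and
   Group-B data.

## Latent models

Both variants embed a standardized 192 × n matrix into z ∈ R².

**Res-SSAAE.** Encoder: three residual 1-D convolution blocks with 16, 32
and 64 channels (two kernel-5 convolutions per block, batch norm + ReLU,
dropout 0.1, additive skip; a 1 × 1 projection on the skip path only where
channel counts change), max-pool 2 between blocks, then dense 128 (batch
norm, ReLU, dropout) and a linear 2-unit output. Decoder mirrors the
encoder with nearest-neighbour upsampling. Discriminator: two dense
layers of 512 sigmoid units and a scalar logit output. The discriminator
deliberately has **no batch normalization**: normalizing mixed real/fake
batches absorbs exactly the distribution shift the encoder must learn,
and in our experiments stalled the adversarial game completely.

**Cond-SSAAE.** Identical, plus the activity label passed through an
8-unit embedding concatenated to the encoder input (broadcast along time
as extra channels) and to the decoder input. It requires the label at
inference and is a cluster-analysis rather than predictive model.

**Semi-supervised adversarial regularization.** The prior is a mixture of
four isotropic Gaussians, one per activity, with modes equally spaced on
a circle (defaults radius 4, SD 1). Per batch, three updates alternate:
(1) reconstruction — encoder+decoder minimize MSE; (2) discriminator —
"real" latent points are drawn from each item's *labelled* mode, paired
with the one-hot label as a side input, against the encoder's outputs
with the same labels; (3) generator — the encoder is updated to fool the
discriminator. At equilibrium each activity forms one Gaussian cluster
at its own mode.

**Epoch selection and fine-tuning.** After every epoch, a Gaussian is
fitted to the validation encodings of each activity and its closed-form
KL divergence to that activity's prior mode is computed; weights from the
epoch with the lowest mean KL are kept (early stopping by KL). The kept
model is then fine-tuned on Group B for 10 epochs at one tenth of the
base learning rate before Group-B encoding.

**Optimization.** Adam, default learning rate 1e-4, batch size 64, up to
300 epochs. Two additions stabilize the game without changing the loss:
a discriminator warm-up (300 steps before the first encoder update, so
the label-conditional decision surface exists before clusters commit to
modes) and optional KL-gated restarts (`n_restarts`): training reruns
from derived child seeds and keeps the run with the lowest validation KL,
accepting early when KL ≤ 6. Both use only the validation KL already
used for model selection.

**Scaled runs.** The test suite and the acceptance script use reduced
problem sizes: 10 Group-A subjects, 3–5 Group-B subjects, 6–10 sets per
exercise, 25–40 epochs, batch 16, learning rate 1e-3 with up to 3
restarts. The larger learning rate compensates for the much smaller
optimizer-step budget; the package default remains 1e-4.

**Latent accuracy** is the fraction of encoded points whose nearest prior
mode (Euclidean) is the true activity's mode.

## Cluster-drift indices

Each set of 10 repetitions forms a cluster of 10 latent points. Four
indices quantify drift, three of them comparing set *i* ≥ 1 with the
initial set 0:

* **Silhouette** of the 2-cluster labelling (mean over all points;
  identical point sets score 0 by convention);
* **Davies–Bouldin**: with two clusters the average of maximum
  similarities reduces to (S_i + S_0)/d(c_i, c_0), where S is the mean
  distance of points to their own centroid — implemented directly, with
  the general k-cluster form available behind the same interface;
* **95% confidence-ellipse area** of each set alone: π · χ²₂(0.95) ·
  √det(Σ̂) with the sample covariance Σ̂ (≈ 18.82 for unit covariance);
  the χ² quantile is exact under the assumed bivariate normality, with no
  small-sample correction;
* **centroid distance** between set i and set 0.

Degenerate geometry (coincident centroids for Davies–Bouldin, singular
covariance for the ellipse) yields flagged missing records rather than
aborting a participant; downstream regressions drop flagged rows.

## Trend analysis

Within each participant's (exercise, index) series, values are z-scored;
set position maps to completion percentage 100·i/(S−1) so the last set
("complete fatigue") is 100%. For each (exercise, index) cell the
standardized values of all participants are pooled and regressed on
completion by OLS; significance is the two-sided t-test on the slope at
α = 0.05 (no multiple-testing correction by default; a Benjamini–
Hochberg helper is provided). With K folds this gives K × 4 × 4
fold-level regressions per variant (64 at K = 4), counted as the
"p-value counter"; averaging each (participant, exercise, set, index)
value across folds first gives the 16 "ensemble" regressions.

A property worth knowing: per-participant z-scoring followed by pooled
OLS is mildly anticonservative at very small set counts (empirical null
size ≈ 0.06 at 4–6 sets per participant, ≈ 0.05 at 6–10 in simulation),
because the within-participant centering and scaling consume degrees of
freedom the pooled t-test does not account for. The procedure is kept as
published; analyses with very short set series should read borderline
p-values accordingly.

## Synthetic cohorts

No public dataset accompanies the protocol, so the generator produces
cohorts with the statistical structure the analysis assumes, not
biomechanically faithful signals. Each exercise has a deterministic
template (sums of low-frequency harmonics with exercise-specific spectra
for board force, CoP and per-sensor IMU channels); the left lunge is the
mediolateral mirror of the right (vectors flip y; angular rates, being
pseudovectors, flip x and z; the forearm sensors swap). The lunges'
board signature is nearly identical (mediolateral CoP amplitude 3 mm,
below the 4 mm simulated postural-sway floor) so board-only data cannot
separate them well, while the forearm IMUs can — reproducing the
qualitative sensor-combination ordering of the study. Participants carry
random amplitude (SD 8%) and duration (SD 7%) effects; anthropometrics
are drawn from the two groups' reported means and SDs. Repetition
durations are 2.0 s (squat/lunges) and 1.5 s (plank jump-in). Corner
forces are the unique symmetric solution reproducing the target total
force and CoP moments; baseline sensor noise (acc 0.15 m/s², gyro
0.05 rad/s, force 5 N) is always present.

Fatigue enters through a five-parameter profile applied in proportion to
the completion fraction i/(S−1): amplitude drift (default +50% at
exhaustion), sensor-noise growth (+30%), phase jitter (SD 3% of the
cycle), CoP sway growth (+80%) and an 8–12 Hz tremor component
(0.2 m/s²). The defaults make the *pattern shift* dominate dispersion
growth, because that balance reproduces the reported direction structure
of the indices (ellipse area, centroid distance and silhouette increase;
Davies–Bouldin decreases): with dispersion-dominated drift the
Davies–Bouldin index rises instead, as the centroid displacement stays
below the cluster-centroid sampling noise. The all-zero profile is
exactly stationary across sets (the null model), and each parameter,
varied alone, moves its matched raw-signal statistic monotonically.

What passing tests on these cohorts do **not** show: robustness to real
sensor artefacts (drift, saturation, dropped samples), to imperfect
manual segmentation, to non-stationary motor strategies unrelated to
fatigue, or to inter-individual variability beyond scalar amplitude and
duration effects.

## Numerical and engineering choices

* All repetitions resample to 192 frames; inputs to the models must be
  divisible by 2³.
* Networks run in float32 (NumPy, BLAS matmuls via im2col); gradients are
  verified against central differences in float64 in the test suite.
* The Gaussian KL uses the sample covariance regularized by 1e-9·I when
  near-singular; it requires ≥ 3 points.
* Seeding: a master seed spawns per-(participant, exercise, set,
  repetition) child seeds by stable hashing, so any sub-cohort is
  reproducible independently of generation order; all derived seeds stay
  below 2³¹.
* Cohorts are plain CSV (17-significant-digit floats, lossless
  round-trip) plus a JSON manifest; experiment artifacts are CSV/JSON and
  re-runs skip stages whose outputs exist under an unchanged
  configuration hash.

## Known limitations

* The generator encodes the *hypothesised* fatigue signature; effect
  sizes are design choices, so absolute counter values on synthetic data
  are not comparable to any real cohort's.
* Adversarial training on very small folds can still fail for an unlucky
  seed when restarts are disabled; the validation-KL value flags such
  runs (KL ≫ 6).
* The conditional variant needs the activity label at inference; it
  cannot be used for activity recognition.
* Fold-level regressions treat pooled standardized points as independent
  (see the anticonservativity note above); mixed-effects alternatives are
  out of scope.
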