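# fatlat — latent-space fatigue assessment of exercise repetitions

`fatlat` studies how muscular fatigue changes motor control during
repeated exercise, using wearable-sensor recordings: a balance board
(vertical corner forces at 30 Hz) and three IMUs (hip and both forearms,
accelerometer + gyroscope at 60 Hz). It is written for movement
scientists and sports-science engineers who want a tested, end-to-end
reference pipeline for latent-space fatigue analysis — and, because the
original cohort is not public, it ships a synthetic-cohort generator
that reproduces the study's statistical structure.

## The method

Each repetition of an exercise (Squat, Lunge Left, Lunge Right, Plank
Jump-in) becomes a standardized matrix **X** ∈ R^{192×n}: corner forces
are converted to mass-normalized ground-reaction force and initial-
subtracted centre of pressure, IMU streams are T-pose calibrated,
gravity-removed and height-normalized, everything is low-pass filtered
(zero-phase Butterworth, 15 Hz, order 4), cubic-spline resampled to 192
frames and z-scored per signal type with statistics from the training
subjects only. `n` depends on the sensor combination (DB0 board only,
n = 3 … DB4 three IMUs, n = 18).

A semi-supervised adversarial autoencoder embeds X into **z** ∈ R². The
encoder is adversarially regularized toward a mixture of four Gaussians
— one mode per activity on a circle of radius 4 (SD 1) — by a
discriminator that sees latent points together with their one-hot
activity labels. A conditional variant additionally feeds an activity
embedding to encoder and decoder. Training selects the epoch whose
validation encodings have the lowest mean KL divergence
KL(N(m̂, Σ̂) ‖ N(μ_c, I)) across activities, then fine-tunes on the
fatigue group at lr/10.

Each set of 10 repetitions yields a cluster of 10 latent points. Fatigue
drift is quantified by four indices — silhouette and Davies–Bouldin of
set *i* vs set 0, the 95% confidence-ellipse area π·χ²₂(0.95)·√det Σ̂,
and the centroid distance — standardized per participant, mapped to a
completion percentage 100·i/(S−1), and regressed on completion by OLS.
With K folds, K×4×4 regressions feed a significance counter (p < 0.05);
fold-averaged indices give 16 "ensemble" regressions per model variant.

## Worked example

```python
import numpy as np
from fatlat import synthio, orchestrate

config = orchestrate.ExperimentConfig(
    cohort=synthio.GeneratorConfig(n_group_a=10, n_group_b=3,
                                   sets_range=(6, 9), seed=42),
    databases=["DB3"], variants=["res"], k_folds=2, seed=42,
    training=orchestrate.TrainingConfig(max_epochs=35, batch_size=16,
                                        lr=1e-3, n_restarts=2),
)
assessment = orchestrate.run_experiment(config, "scratch/demo")
print(assessment[["db", "variant", "p_value_counter", "counter_total",
                  "p_value_ensemble", "ensemble_total"]].to_string(index=False))
```

prints, after a few minutes of CPU training (numbers vary with the seed):

```
 db variant  p_value_counter  counter_total  p_value_ensemble  ensemble_total
DB3     res               25             32                13              16
```

meaning that 25 of the 32 fold-level index-vs-completion regressions and
13 of the 16 ensemble regressions are significant at α = 0.05 — the
synthetic fatigue drift is detected in the latent space. The output
directory also holds the Group-B latent coordinates (`latents.csv`), the
per-set index table (`indices.csv`), all regression results
(`trends.csv`, `ensemble.csv`) and latent-space scatter figures.

The estimator layer composes with scikit-learn:

```python
from fatlat import AdversarialAutoencoder
model = AdversarialAutoencoder(conditional=False, max_epochs=40,
                               batch_size=16, lr=1e-3, random_state=0)
model.fit(X_train, y_train, X_val=X_val, y_val=y_val)   # (R, 192, n) arrays
z = model.transform(X_val)                              # (R, 2) latent points
print(model.score(X_val, y_val))                        # latent accuracy
```

A thin CLI mirrors the stages: `fatlat simulate`, `fatlat preprocess`,
`fatlat indices`, `fatlat trends`, `fatlat run-all` (see `--help`).

## Data formats

A cohort directory holds `manifest.json` plus one CSV per repetition
(`data/<participant>/<exercise>/set<k>_rep<j>.csv`, timestamps and one
column per channel with units in the header) and a per-session T-pose
CSV. Any dataset in this layout — synthetic or recorded — can enter the
pipeline. See `docs/methods.md` for the model, generator and statistical
details.
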