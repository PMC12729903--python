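# gaitrec

Longitudinal clustering of post-stroke gait recovery trajectories.

After a stroke, hemiplegic patients recover walking function along very
different courses. Given sagittal joint-angle trajectories (hip, knee,
ankle angle and angular velocity, time-normalized to 100 samples per gait
cycle) collected at 8 follow-up assessments (2-24 weeks post-onset), this
package identifies data-driven *recovery archetypes* and validates them
statistically. It is aimed at rehabilitation researchers and methods
developers who need a reproducible, fully testable version of this
analysis — including a synthetic-cohort generator with planted ground
truth, since clinical datasets of this kind are rarely shareable.

## The pipeline

Each patient is a tensor `X ∈ R^{8x600}` (weeks x concatenated channels)
with a week-level observation mask `M`.

1. **Imputation** (bidirectional recurrent, BRITS-style). Estimates
   `X̂_t = W η_{t-1} + b` from a GRU hidden state, merges
   `X^c_t = M_t ⊙ X_t + (1-M_t) ⊙ X̂_t`, and minimizes
   `Σ_t M_t ⊙ ||X_t - X̂_t||²` self-supervised by masking observed weeks;
   missing weeks get the mean of forward and backward estimates.
2. **Augmentation.** A time-series VAE (`z = μ + σ ⊙ ε`) and a DDPM
   alternative (`x_t = √ᾱ_t x_0 + √(1-ᾱ_t) ε`) generate synthetic
   patients at ratio 5 (31 real → 186 samples).
3. **Fidelity screen.** Kernel two-sample test:
   `MMD²(P,Q) = E[k(x,x')] + E[k(y,y')] - 2E[k(x,y)]` with an RBF kernel,
   median-heuristic bandwidth, and a plus-one-corrected permutation
   p-value; plus a UMAP overlay for visual review.
4. **Deep temporal clustering.** Conv1D → max-pool → Bi-LSTM(50) →
   Bi-LSTM(1) autoencoder with a Student-t soft-assignment layer
   `q_ij ∝ (1+||z_i-μ_j||²)^{-1}`, trained end-to-end on
   `L = L_rec + KL(P‖Q)`.
5. **Model selection.** The Balanced Silhouette Score
   `BSS = (1-α)·(SS+1)/2 + α·H/log K` (α = 0.15) combines silhouette
   quality with cluster-occupancy entropy; a random hyperparameter search
   over K = 3..10 keeps the argmax.
6. **Validation.** Peak kinematics (hip extension, knee swing flexion,
   ankle terminal-stance dorsiflexion), week-specific RMSE versus a
   normative reference split by stance/swing phase, and a two-way mixed
   ANOVA (group x week interaction). A noncentral-t solver performs the
   a-priori sample-size computation.

All neural models run on a small built-in numpy autodiff engine
(`gaitrec.nn`) — no deep-learning framework required — and every fit is
bit-reproducible from its seed.

## Worked example

```python
from gaitrec.synthetic import CohortSpec, generate_cohort
from gaitrec.imputation import BritsImputer, ImputerConfig
from gaitrec.augmentation import TimeSeriesVAE, VAEConfig, augment_cohort
from gaitrec.assessment import permutation_test

cohort = generate_cohort(CohortSpec(seed=0))     # 31 patients, 8 weeks, 600 features
print(cohort.values.shape, int((cohort.mask == 0).sum()))

imputer = BritsImputer(ImputerConfig(epochs=150, seed=0)).fit(cohort)
completed = imputer.impute(cohort)
print(int((completed.week_provenance == "imputed").sum()), "weeks imputed")

vae = TimeSeriesVAE(VAEConfig(epochs=400, seed=0)).fit(completed)
combined = augment_cohort(completed, vae, ratio=5, seed=0)
res = permutation_test(
    combined.values[:31].reshape(31, -1),
    combined.values[31:].reshape(155, -1),
    n_permutations=200, seed=0,
)
print(combined.n_patients, round(res.mmd2_obs, 4), round(res.p_value, 3))
```

Output:

```
(31, 8, 600) 59
59 weeks imputed
186 0.0085 0.507
```

The cohort reproduces the study bookkeeping — 59 of 248 patient-weeks
(~24%) missing under the default missingness profile — the imputer fills
exactly those 59 weeks, and the augmented cohort of 186 samples passes
the MMD screen (p = 0.507 > 0.05: no detectable distributional shift
between real and synthetic trajectories).

The same stages are available from the shell:

```bash
gaitrec simulate --n-patients 31 --seed 0 --out run/cohort
gaitrec impute --in run/cohort --out run/imputed --seed 0
gaitrec augment --in run/imputed --method vae --ratio 5 --out run/augmented --seed 0
gaitrec select-k --in run/augmented --k-min 3 --k-max 10 --out run/selection.csv
gaitrec run-all --seed 0 --out run/all     # full pipeline + manifest
```

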