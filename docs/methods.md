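# Methods

This package re-implements, as a tested pipeline over synthetic cohorts, a
longitudinal analysis of post-stroke gait recovery: sagittal joint-angle
trajectories collected at 8 follow-up assessments are imputed, augmented
with a generative model, clustered with a deep temporal clustering network,
and the resulting recovery groups are statistically validated.

## Data model

A patient is one multivariate time series of shape `8 x 600`: the sequence
axis is the assessment week (2, 3, 4, 6, 8, 10, 12, 24 weeks post-onset)
and the feature axis concatenates six channels — hip, knee and ankle
sagittal angle plus angular velocity — each time-normalized to 100 samples
per gait cycle. A cohort is the stacked `[N, 8, 600]` tensor with a
week-level observation mask. Missingness is always week-level: an
assessment either produced a full 600-vector or nothing.

## Synthetic cohort generator

Clinical gait recordings of this kind are not publicly deposited, so every
stage is exercised on simulated cohorts with known ground truth. The
generator emulates:

- **Normative cycles.** Fixed low-order Fourier curves per joint (two
  harmonics), qualitatively matching textbook sagittal kinematics: hip
  flexes early and extends mid-late stance; knee shows a small
  stance-flexion wave and a dominant swing-flexion peak (~55-60 deg near
  60-65% of the cycle); ankle dorsiflexion peaks in terminal stance.
  Velocity channels are analytic derivatives of the angle curves (degrees
  per sample), so channel semantics are exact rather than
  finite-difference approximations of noisy angles.
- **Recovery archetypes.** Each patient belongs to an archetype defined by
  a periodic deviation bump (von Mises shape; phase and width in cycle
  fraction), per-channel deviation amplitudes (degrees), and a per-week
  exponential recovery rate `r`. Week `w` reads
  `normative + A_c * exp(-r (w - w0)) * g(t) + noise`, i.e. pathology
  decays multiplicatively toward the normative cycle at an
  archetype-specific rate. The deviation of a velocity channel is the
  analytic derivative of the bump. The functional form is the package's
  own choice; recovery dynamics in the source domain are described only
  qualitatively.
- **Noise.** I.i.d. Gaussian noise per sample, default `noise_sd = 2.0`
  degrees — a typical inter-trial variability for joint-angle
  measurements. The default archetype bank spreads bump phases over the
  cycle, alternates deviation signs, and spaces recovery rates between
  0.05 and 0.5 per week, giving well-separated planted clusters.
- **Missingness.** A `{missing-week-count: patient-count}` profile,
  default `{0:7, 1:6, 2:5, 3:9, 4:4}` over 31 patients, which masks
  exactly 59 of 248 patient-weeks (~24%). Weeks to drop are chosen
  uniformly (missing-completely-at-random); the first assessment is
  always kept as an anchor, since all study patients had at least four
  recorded assessments. The generator leaves the simulated ground truth
  under the mask — the mask is authoritative, consumers must not read
  masked rows — so tests can score imputation against held-out truth.

What the generator does *not* emulate: biomechanical coupling between
joints, severity-dependent (informative) missingness, spatiotemporal gait
parameters, non-sagittal planes, and measurement artifacts such as marker
occlusion. Passing tests therefore demonstrate the pipeline's correctness
and its behavior on cluster-structured longitudinal data, not clinical
validity on real recordings.

## Neural components

No deep-learning framework is used; all four models run on a compact
reverse-mode automatic-differentiation engine over float64 numpy arrays
(`gaitrec.nn`), with dense, Conv1D (im2col), GRU, bidirectional LSTM,
max-pool and upsampling primitives, Adam, and global gradient-norm
clipping. All parameter initialization and stochastic training draws go
through seeded `numpy` generators, making every fit bit-reproducible.
Numerical gradient checks for every primitive are part of the test suite.

### Recurrent imputation

A bidirectional recurrent imputer in the style of BRITS runs over the
8-step week axis (features = 600): at each step a linear read-out predicts
the week vector from the previous hidden state, the complement operation
`X_c = M*X + (1-M)*Xhat` merges observations with estimates, and a GRU
(hidden 64) consumes the merged vector plus the step's observation flag
and the normalized gap to the previous assessment week (weeks are
irregular). Training is self-supervised: each epoch hides a fraction
(default 0.1) of observed patient-weeks, and the loss is the mean squared
error on observed entries for both directions plus a forward/backward
consistency penalty at missing steps (weight 0.1). Inputs are
standardized per feature over observed rows. The final imputation is the
mean of the forward and backward estimates; observed weeks pass through
bit-exactly, and a per-week provenance flag (`observed`/`imputed`)
accompanies the completed cohort. The monitored loss history is an
end-of-epoch evaluation with the full observed mask, which is
deterministic (the training objective itself resamples the artificial
mask). On default synthetic cohorts the imputer's held-out MSE is close
to the irreducible noise floor and clearly below per-patient linear
interpolation across weeks.

### Generative augmentation

The primary generator is a time-series VAE: a Conv1D encoder over the
week axis (3 blocks, 32 filters, Leaky ReLU) maps a standardized `8x600`
tensor to a Gaussian latent (default width 2), sampling uses the
reparameterization `z = mu + sigma .* eps`, and a mirrored decoder
reconstructs. The loss is per-sample summed reconstruction error plus the
closed-form Gaussian KL; because reconstruction sums over 4800 dimensions
while KL sums over 2, posterior collapse is not a practical concern. The
encoder's log-variance is squashed to [-10, 10] for numerical safety on
out-of-distribution inputs. Defaults: learning rate 1e-4, batch 64,
latent 2, layers 3 (the selected values of the source tuning table);
epochs default to 1000 as a desk-scale stand-in for the table's 10,000,
and remain configurable.

Augmentation at ratio `r` (default 5, giving 31 real + 155 synthetic =
186 samples) pairs each real patient with `r` decodes of latents drawn
from that patient's posterior, keeping each synthetic sample a plausible
variation of a specific recovery course; unconditional prior sampling is
also exposed. Whether the original analysis sampled conditionally or
unconditionally is unstated; conditional posterior sampling is this
package's default design choice.

The alternative generator is a standard DDPM: the stepwise corruption
kernel with schedule `beta_t` implies the closed-form marginal
`x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps`, which is used for
training an epsilon-predicting Conv1D network (sinusoidal time embedding
appended as channels); the reverse sampler fixes the variance to
`beta_t I`. Default schedule: linear 1e-4 to 0.02 over 100 steps. The
full interpretable-transformer architecture of published time-series
diffusion models is intentionally out of scope.

### Fidelity testing

Augmentation quality is tested with the squared maximum mean discrepancy
between flattened real and synthetic samples (4800-D), RBF kernel with
the median heuristic on the pooled sample, computed as a biased
V-statistic (identical sets score exactly 0; an unbiased U-statistic
switch exists). Significance uses label-shuffling permutations with the
plus-one correction `p = (1 + exceedances) / (n_perm + 1)`; the bandwidth
is computed once on pooled data and reused across permutations.
`n_permutations` defaults to 999 (the source count is unstated). A
seeded UMAP overlay provides the qualitative companion view.

### Deep temporal clustering

The encoder is Conv1D (Leaky ReLU) along the week axis, max-pooling with
pool size from {2, 4, 6, 8} (right-padded so the latent length is
`ceil(8 / pool)`), then Bi-LSTM(50) and Bi-LSTM(1) — fixed hidden sizes —
giving a latent sequence of width 2. The decoder upsamples
(nearest-neighbour) and applies two Conv1D layers back to 600 features;
upsample+conv is the standard equivalent of the upsample+deconvolution
description. Cluster membership is the Student-t soft assignment
`q_ij ∝ (1 + ||z_i - mu_j||^2)^-1` on flattened latents; centroids are
initialized by complete-linkage agglomerative clustering of pretrained
latents (ward/average configurable). Training is two-phase and
full-batch: autoencoder pretraining (150 epochs, MSE), then joint
optimization (100 epochs) of reconstruction MSE plus the KL divergence to
the deep-embedded-clustering target
`p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j')`, refreshed every epoch,
with an epsilon floor of 1e-12 inside logarithms. The target definition is
the largest interpretive choice in the package: the source defines the
clustering loss but never writes `p_ij`; the standard DEC target is
adopted. Note the frequency correction `1/f_j` means the target is
guaranteed to sharpen assignments only when occupancies are balanced.
Hard labels are `argmax_j q_ij`, with a majority-vote aggregation across
a patient's synthetic replicates for patient-level labels.

## Model selection

For each candidate K (default 3-10), random search samples the learning
rates (log-uniform over the published ranges: TAE 5e-3 to 1e-2, clustering
5e-4 to 5e-3) and the pool size; each trial trains the full model and is
scored by the Balanced Silhouette Score on the model's own latent
geometry:

    BSS = (1 - alpha) * (SS + 1)/2 + alpha * H / log K,   alpha = 0.15.

The normalizations — affine for silhouette from [-1, 1], ratio for
entropy against its maximum log K — are the natural maps onto [0, 1]; the
source states only that both terms are normalized. A sample alone in its
cluster scores 0 (standard convention), and a fully collapsed
single-cluster solution is assigned BSS = 0 so the search can rank it
instead of erroring. Ties on the per-K maximum break toward smaller K.
Desk default is 20 trials (the source ran 300 Bayesian-optimization
trials); the acceptance checks use 2 trials per K with the full 150/100
epoch schedule, which recovers the planted K = 6 on well-separated
archetypes in a few minutes on one CPU.

## Statistical validation

Phase windows on the 100-point cycle: stance [0%, 60%), swing
[60%, 100%), terminal stance [30%, 60%) — the source names the phases but
not the bounds; these follow standard gait nomenclature and are
configurable. Features per patient-week: peak hip extension (full-cycle
minimum of the flexion-positive hip angle; sign convention recorded
here), peak knee flexion within swing, peak ankle dorsiflexion within
terminal stance, and per-joint RMSE against the normative reference,
split by stance/swing. Analysis weeks default to {2, 3, 4, 6, 8, 10, 12}
(the final follow-up is excluded from the week-specific deviation
analysis, as in the source; a flag includes it). Only real patients enter
inference by default; synthetic replicates are excluded.

The two-way mixed ANOVA (group between-subject, week within-subject,
interaction of interest) is delegated to `pingouin.mixed_anova` — a
standard procedure, not this package's contribution — behind a module
surface that validates the design (each subject in exactly one group,
balanced complete weeks, at least two groups). The independent oracle in
the tests is a frozen base-R `aov(value ~ group*week + Error(subject))`
result on a balanced fixture, plus a direct sums-of-squares partition
check and type-I/power simulations. No sphericity correction is applied
by default (the source does not mention one); it is available via the
underlying routine.

The a-priori sample-size computation solves the noncentral-t power
equation by iterating n upward: with `d = 0.187/0.3`, two-tailed
alpha 0.05 and power 0.95, the one-sample/paired design yields n = 36 —
reproducing the published figure — while a true independent two-sample
design would require ~68 per group; both designs are implemented and the
paired one is the default because it is the computation consistent with
the published number.

## Pipeline and reproducibility

`run_all` executes the six stages (simulate, impute [with moving-average
smoothing, default window 5, symmetric padding, applied per channel per
week before imputation], augment, assess, select-K, validate), writing
delimited-text artifacts and a manifest with per-stage seeds, SHA-256
output hashes and timings. Every stage seed derives from the global seed
via CRC32 of `"<seed>:<stage>"`, so identical configs give byte-identical
outputs. Cohorts serialize as long-format CSV (masked weeks as empty
fields, the mask file authoritative) with a YAML layout sidecar.

## Desk-scale problem sizes

Tests and examples run at reduced sizes chosen to keep the full suite
fast while preserving the phenomena under test: imputer 40-150 epochs,
VAE 30-600 epochs, diffusion 150-1000 epochs, DTC 150/100 epochs (the
published schedule) for recovery checks and 2 search trials per K for
selection; cohorts of 12-48 patients for clustering checks and the
31-patient study layout for bookkeeping, imputation and augmentation
checks. The published epoch counts and trial budgets remain available
through the configs.

## Known limitations

- The generator's archetypes are geometrically convenient (single-bump
  deviations, exponential recovery); real hemiplegic gait deviates in
  more structured, multi-phase ways.
- MCAR missingness only; informative missingness would stress the
  imputer differently.
- The diffusion generator is a deliberately plain DDPM and, at small
  sample sizes, produces lower-fidelity cohorts than the VAE — matching
  the qualitative ordering reported for the source's generators.
- BSS is computed on the clustering model's own latent geometry, which
  adapts during joint training; under-trained models can make competing
  K values hard to distinguish (visible in the tests as a requirement
  for the full epoch schedule during selection).
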