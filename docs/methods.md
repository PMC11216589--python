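# Methods

## The measurement

A *neuronal model* is a feature layer plus a fitted linear readout. Given a
layer's activation matrix `X` (stimuli × units) and a site's trial-averaged
responses `y`, the pipeline fits a partial-least-squares (PLS) regression
under k-fold cross-validation on the in-distribution (ID) stimulus domain
and scores it two ways:

- **ID score** — Pearson correlation between held-out predictions, pooled
  across folds, and the held-out measurements (one correlation per
  cross-validation repetition). Pooling was chosen over averaging per-fold
  correlations because folds of a few dozen stimuli give unstable per-fold
  correlations; the per-fold-average variant is available via
  `CVConfig(pool_folds=False)`.
- **OOD score** — predictions of all k fold models on *every*
  out-of-distribution (OOD) stimulus are averaged per stimulus, then
  correlated with the OOD measurements, again per repetition.

Fold assignment is a uniform random partition (no stratification) seeded
`seed + repetition`, so repetitions are independent but the whole procedure
is reproducible bit for bit. Population summaries take the median across
sites within each repetition, then the mean across repetitions.

Defaults follow the conventions of the source experiments: 10 folds, 25 PLS
components, 5 repetitions. The PLS is a NIPALS PLS2 with centered (not
variance-scaled) predictors and responses, fitted jointly over all sites of
a session; the inner power iteration runs essentially to its numerical
fixed point (tolerance 1e-24) so scores do not depend on convergence
conventions. `CVConfig(per_site=True)` refits a single-response PLS per
site — mathematically distinct from the joint fit and useful when a site's
score must not depend on the other sites (see *Invariances*).

### Layer mappings

- **Layer–area**: for each layer, median ID score across sites per
  repetition, averaged over repetitions; the argmax layer is assigned to
  every site.
- **Layer–neuron**: each site gets the layer with the highest
  repetition-averaged ID score for that site.

Ties break to the earliest layer. Both mappings select on ID scores only,
so OOD results remain genuine generalization measurements. On the per-site
selection scores, the layer–neuron median dominates the layer–area median
exactly (a pointwise max dominates any common choice); this is a theorem,
and the test suite checks it without tolerance.

### The generalization gap

Two readings of the gap are reported side by side:

- `c_gap = C_nat − C_syn`, the difference of the two population scores;
- `c_gap_sitewise`, the mean over repetitions of the median across sites of
  per-site (ID − OOD) score differences.

They coincide for a single site and usually agree closely, but the median
of differences is not the difference of medians; analyses of gap behavior
in this package use `c_gap_sitewise` (the procedural reading), while
`c_gap` preserves the identity with the two population scores.

Note that ID and OOD scores are not perfectly symmetric measurements: the
ID score correlates single-fold held-out predictions while the OOD score
correlates k-fold-averaged predictions, whose noise is partially averaged
out. Under a null configuration this produces a small *negative* bias of
the gap (≈ −0.01 at the default desk scale), which the null-gap check
absorbs within its ±0.05 band.

### Reliability

Internal consistency of a site is estimated by splitting its
repetition × stimulus response matrix into random half/half repetition sets
(⌊n/2⌋ / ⌈n/2⌉ for odd n — no trial is discarded), correlating the two
half-mean response profiles, applying the Spearman–Brown correction
`2c/(1+c)`, and taking the median over 100 splits. Each site uses a seed
derived by hashing (base seed, site id), so results are independent of
processing order. Sites with corrected reliability ≤ 0.7 (strict
inequality for retention) are excluded before scoring. Under the
generator's noise model the expected split-half correlation has the closed
form `c = s²/(s² + 2σ²/n)` for signal variance s², trial-noise variance σ²
and n repetitions; `noise_sd_for_reliability` inverts it, and the test
suite verifies the simulated median against it to ±0.01.

### Agreement and ensembles

Score consistency is the Pearson correlation between two models' per-site
score profiles. Prediction consistency correlates two models'
per-stimulus predictions for one site, restricted to model pairs whose
scores differ by ≤ 0.02 (absolute; a relative mode exists) so that
disagreement is about *how*, not *how well*, the site is predicted.

Ensembles aggregate stored per-repetition fold predictions (never refit):
within-model ensembles take the top-k layers per site by ID score;
cross-model ensembles take the top-k layers within each of the top-k models,
with models ranked by their layer–neuron population ID score. Aggregation
is the per-stimulus mean or median of raw predicted responses — no
per-member standardization, since Pearson scoring is affine-invariant and
only the median would be affected.

## The synthetic-data generator

The generator emulates the *structure* of a two-domain primate
electrophysiology experiment without rendering images:

- **Stimuli** are latent vectors (default dimension 8). ID latents are
  standard normal; OOD latents are `N(offset, cov_scale·I)`. A small
  `cov_scale` with a nonzero offset emulates a narrow, displaced synthetic
  stimulus domain.
- **The feature hierarchy** is a random multi-layer network (default 4 ReLU
  layers of 50 units). Mixing matrices are standardized at construction so
  every unit's pre-activation is approximately zero-mean/unit-variance on
  ID latents, keeping activation variances within [0.1, 10].
- **Sites** are sparse linear readouts of one hidden layer, rescaled to
  unit signal SD over the ID stimuli, plus a baseline (default 5) that
  keeps firing rates positive. Trials are mean + independent Gaussian noise,
  rectified at zero; with the default baseline ≥ 5× the noise SD,
  rectification touches < 0.1% of trials. Repetition counts are drawn once
  per session-domain, uniformly in 31–51 by default.
- **Out-of-distribution misspecification** comes in two flavors: a relative
  perturbation of the readout weights, or generation from a different layer.
  A pure layer override makes the OOD response function statistically
  independent of the ID one, so `ood_override_mix` blends the two
  (OOD mean ∝ (1−mix)·ID readout + mix·override readout); partial mixing is
  what reproduces asymmetric cross-domain transfer.

Default sizes (160 ID + 80 OOD stimuli, 300 reference stimuli, 40 sites)
are deliberately desk-scale; the configuration accepts the full
experimental sizes. The reference stimuli used for basis fitting are drawn
from a third ID-like distribution, distinct from the scored stimulus set.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated trial-to-trial noise across sites,
temporal response structure (a single rate per trial), the image-specific
statistics of natural versus optimized synthetic stimuli, and the internal
structure of real pretrained networks. One concrete consequence: generating
OOD responses from a deeper layer does *not* shift the best-OOD-layer
offset here, because OOD scores are transfers of ID-fitted models and a
readout from another layer is simply unpredictable by all of them; the
negative offsets reported on real recordings reflect network/stimulus
structure outside this generator's scope. The offset analysis is therefore
verified against brute-force oracles on fixtures rather than by generative
recovery.

## Invariances and numerical choices

- Scores are invariant (1e-10) to a shared positive affine rescaling of
  all responses in the joint fit, and to per-site affine rescalings in the
  per-site fit. The joint PLS2 is *not* invariant to rescaling a single
  site, since all sites shape the shared components — an inherent property
  of multi-response PLS worth knowing before comparing sessions recorded at
  different gains.
- Predictions are invariant (1e-8) to orthonormal rotations of the
  predictor columns, so a full-rank PCA projection (a rigid rotation after
  centering) reproduces no-PCA scores to 1e-6.
- Undefined correlations (zero-variance predictions or measurements) are
  recorded as missing and excluded from medians, never coerced to zero.
- PCA retains `min(n_reference − 1, n_units, 500)` components by default,
  centering only, with each component's largest-magnitude loading forced
  positive for reproducibility.
- Requested PLS components are clipped to the training-fold rank with a
  warning.
- The pooled cross-validated correlation has a small negative bias under
  the null (≈ −0.05 for 200 stimuli, 5 folds) because each fold's model
  depends on the other folds' targets through the training means; the
  Monte-Carlo null test bounds |mean| by 0.1 accordingly.

## Problem sizes used in tests

The suite runs simulations at reduced scale chosen as the smallest sizes at
which each property is statistically stable: scoring worlds of 80–160 ID
stimuli and 12–40 sites, 5–10 folds, 2–3 repetitions, 15–25 components;
the fit-domain-asymmetry harness uses 30 sites × 100 stimuli per domain ×
3 repetitions per seed across 10 seeds. The reliability harness (50 sites,
40 repetitions, 200 stimuli) matches the analytic setting exactly.
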