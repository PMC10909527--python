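# Methods

## The model

`affectspace` studies the joint organization of subjective affect reports and
autonomic responses across emotional events. Each trial — one participant
viewing one normed emotional image — yields five quantitative measurements:
subjective valence and arousal (−10..+10 sliders), baseline-corrected pupil
diameter (mm), phasic skin-conductance amplitude (µS), and a heart-rate
change score (bpm, post-onset mean minus pre-onset mean, so deceleration is
negative).

The synthetic generator plants the structure the analysis is meant to
detect. On a standardized latent scale, each observed variable y for
participant *p* and stimulus *s* is

    y_ps = a1_y · f1_ps + a2_y · f2_ps + (interaction / confound terms)
           + u_p(y) + v_s(y) + e_ps(y)

with two trial-level factors:

* **f1 — shared affect.** Loads on every variable; valence negatively,
  arousal positively (a "negative–arousing" direction). A configurable
  share of its variance (`stimulus_affect_share`, default 0.4) is carried by
  the stimulus's normative affect (a standardized blend of negated norm
  valence and norm arousal), the rest is trial-specific. This is what makes
  stimulus categories separable in the fitted space.
* **f2 — orienting.** Loads only on pupil, SCR and HR: autonomic covariance
  that subjective experience does not track.

Additional structure: crossed random intercepts u_p and v_s per variable; a
brightness confound on pupil (stimulus-level standardized luminance,
coefficient −0.96 by default); a valence×arousal product term on pupil
(+0.16) and SCR (−0.02), where the product uses the population-standardized
subjective latents; a residual valence–arousal correlation (−0.15); SCR is
kept nonnegative by exponentiating its Gaussian latent (log-normal
amplitudes, preserving the monotone link to the factors). Ratings are
scaled by 3.0 slider points per latent SD and clipped to the slider range
(the scale is chosen so clipping affects <0.2% of draws and is negligible
for every moment-based check).

Stimulus norms are drawn from Beta distributions on [1, 9] whose mean and SD
match published normative moments (valence 5.07/1.92, arousal 4.66/1.19),
coupled through a Gaussian copula (correlation −0.3). A bounded Beta is
both more realistic for normative ratings than a censored Gaussian and
leaves the generator's closed-form moments exact. Category labels are
deterministic functions of configurable cut points (valence 4/6; arousal
4/5.3).

### Default loadings and why

Defaults (f1: valence −0.85, arousal +0.85, pupil +0.57, SCR +0.25, HR
−0.49; f2: pupil 0.38, SCR 0.60, HR 0.61; residual SDs 0.45/0.45/0.44/
0.57/0.42; participant SDs 0.35/0.35/0.3/0.3/0.3; stimulus SDs 0.25) were
fixed at design time by matching the *population* factor space — computed
exactly from the implied covariance, see below — to the qualitative
two-dimensional structure the pipeline targets: a first dimension built
jointly by both variable groups (≈57% subjective / 43% autonomic) and a
second dimension carried almost exclusively by the autonomic group (≈3%
subjective), with SCR and HR prominent on it (an orienting profile). Realism
bounds were imposed during that design step: every variable keeps at least
35% unique variance and no loading exceeds 0.7.

### Closed-form implied moments

Every observed variable is a (possibly exponentiated) linear-plus-bilinear
function of one jointly Gaussian latent vector, so all population means and
covariances have exact expressions through Gaussian quadratic-form
identities (for the exponentiated SCR block, through the tilted-Gaussian
measure, which exists iff I − 2ΣA is positive definite — violations raise a
parameterization error). `implied.implied_covariance` /
`implied.population_mfa` are the package's oracles: the planted
eigenstructure, bootstrap coverage targets and structure-recovery checks are
all compared against them rather than against simulations.

## Signal features

Raw-signal mode emits per-trial recordings: pupil at 150 Hz (−1.5..6 s),
SCR at 10 Hz (−1..8 s), HR as a pre/post step series. Feature extraction:

* **Pupil** — samples outside 2–10 mm (or masked) are invalid; invalid runs
  of ≤150 ms are linearly interpolated, longer runs stay excluded;
  subtractive baseline correction over (−1 s, +1 s) around onset (a
  pre-onset-only window is available via `baseline_pre_only`); the feature
  is the mean corrected diameter over 0–6 s. Windows are half-open
  [lo, hi) with a 1 µs grid-jitter tolerance so adjacent windows never share
  a sample.
* **SCR** — trough-to-peak amplitude in the 1–6 s window, computed as the
  maximum drawup (largest value minus running minimum), which equals the
  best trough/peak pair; amplitudes under 0.01 µS (configurable) score 0.
  An optional moving-average smoother stands in for adaptive smoothing; it
  is off by default because the windowed amplitude is the statistic of
  interest.
* **HR** — post-window mean minus pre-window mean (deceleration negative).

The generator scales each waveform on the actual sample grid so that, at
zero noise and zero blinks, extraction reproduces the table features to
machine precision; the closure tests assert <5% relative error. Blinks are
uniform-random gaps of 100–400 ms straddling the 150 ms limit on both
sides.

## Univariate coherence models

Trial-level regressions with crossed random intercepts for participant and
stimulus, fitted by REML (statsmodels MixedLM with variance-component dummy
blocks). The suite: pupil ~ valence*arousal + brightness; scr ~
valence*arousal; hr ~ valence, ~ arousal, and jointly; and the four
cross-signal models (scr~hr, scr~pupil, pupil~hr, pupil~scr). Predictors
are z-scored by default (explicit in `ModelSpec`); p-values use the
large-sample normal approximation and the choice is recorded in the output
metadata. Simple slopes at ±1 SD of a moderator use the delta method on the
fixed-effects covariance. Degenerate variance components report as 0;
singular-Hessian fits flip the `converged` flag rather than erroring.
Brightness is removed from pupil before the multivariate stage by
subtracting the estimated fixed effect only (random-effect structure stays
in the residualized column); `residualize_pupil=False` keeps raw pupil.

## The common space (MFA)

Columns are standardized (population SD, uniform row weights 1/n) and each
group's columns are multiplied by 1/√λ1(g), the inverse square root of that
group's own first PCA eigenvalue, so each group's weighted sub-table has
first eigenvalue exactly 1 and neither group can dominate. The global
eigensystem of the weighted table gives the common dimensions. Derived
quantities: variable–dimension correlations √(λ1(g)·λ_s)·V[j,s], cos², per-
variable contributions 100·V[j,s]² (summing to 100 per dimension), group
contributions, partial row coordinates (G × the row's single-group
projection; their group mean equals the global score exactly), partial axes
(correlations of each group's separate PCA scores with the global scores),
and barycentric projections of supplementary categoricals (plain means of
the global scores — no eigenvalue rescaling; software conventions differ
and the choice is recorded here). Dimension signs are fixed so the
largest-|correlation| variable loads positively. Aggregation variants
(participant, stimulus, participant×category means) re-standardize after
aggregation within each variant.

## Resampling inference

* **Bootstrap.** Default is the two-way ("pigeonhole") bootstrap:
  participants and stimuli are resampled independently with replacement and
  a replicate contains all cells at sampled×sampled combinations. With
  crossed random effects, one-factor cluster resampling understates the
  sampling variability of the eigenstructure — measured on the planted
  design, participant-only resampling covers the population first
  eigenvalue only ~62% of the time at nominal 95%, while the crossed scheme
  achieves ~96% (400-seed characterization); `unit="participant"` and
  `"stimulus"` remain available. Each replicate is refit from scratch and
  aligned to the reference solution (greedy one-to-one matching of loading
  vectors by absolute correlation, with sign flips; greedy equals exhaustive
  matching in the resampling regime). CIs are percentile (.025/.975).
* **Permutation.** Every active column is independently reshuffled within
  strata (default participant × valence category; participant-only
  available), destroying all cross-variable association while preserving
  marginals and stratum composition. The eigenvalue test statistic is the
  dimension's *share of total inertia*: raw eigenvalues are not comparable
  across refits because the group weights adapt to each permuted dataset
  (raw-statistic p-values are returned for reference). One-tailed add-one
  p-values; dimensions are retained by the leading-consecutive rule at α.
* **Reproducibility.** Per-replicate child seeds are spawned from one
  SeedSequence, so results are bit-identical for any parallelism degree.

### Known limitation: permutation under crossed dependence

Within-participant reshuffling assumes trials are exchangeable within a
stratum. Stimulus random intercepts violate this for *any*
within-participant scheme: the permutation null is then slightly too narrow
and the first-eigenvalue test anticonservative (measured rejection ~0.15 at
α=.05 on a fully-null generator with default stimulus intercepts at a
16×12 design). The calibration guarantee therefore applies to the
exchangeable regime (no stimulus-level intercepts), where the measured rate
is 0.044–0.052; a dedicated test documents the inflated crossed regime.
The same caveat applies to any analysis of real data with this scheme.

## Validation of the retained dimensions

A random forest (500 trees, √p features, 70/30 stratified split) predicts
the stimulus valence class from the retained dimension scores; reported are
out-of-bag and held-out accuracy (chance for three balanced classes is
33%), one-vs-rest AUC per class, permutation importance (mean decrease in
accuracy) per dimension, and the chi-square of the held-out confusion
matrix. K-means (25 restarts) over k ∈ [2, 8] is selected by maximum mean
silhouette; reported are the silhouette, percent between-cluster variance,
the cluster×class chi-square and per-cluster standardized variable
profiles. Both trial-level and stimulus-aggregated scores can be supplied.

## Problem sizes and defaults in the test suite

Default inference depth is 10,000 replicates; tests and the acceptance
script run reduced sizes chosen for precision per unit time, as the
package's own verification budget: permutation calibration 250 seeds ×
199 permutations on a 16×12 design; bootstrap coverage 300 seeds × 200
replicates at the full 51×56 design; structure recovery 20 seeds × 199
permutations at 51×56; mixed-model recovery 50 seeds at 51×56 and 60 null
fits at 20×20. Monte-Carlo standard errors at these sizes are quoted in the
relevant test docstrings.

## What the generator does and does not emulate

It reproduces the design (51×56 crossed, one trial per cell), the variable
set and scales, the two-factor covariance structure, category-linked
stimulus affect, a brightness confound, crossed random intercepts, MCAR
missingness, and raw-signal morphology adequate for feature-extraction
closure. It does not emulate: participant-specific loading signs
(individual differences in coherence direction), temporal within-trial
dynamics beyond the stereotyped waveforms, non-MCAR missingness, eye
movements, or the boomerang-shaped valence–arousal norm relationship (a
linear copula correlation stands in). Passing tests therefore certify the
statistical machinery under this structure, not the physiological realism
of any particular dataset.
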