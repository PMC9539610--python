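# Methods

This note documents the statistical procedures implemented in `pupilwm`,
the assumptions behind them, the synthetic-data generator they are
validated against, and the design decisions taken where more than one
reasonable implementation existed.

## The task and the data model

The pipeline targets delayed-estimation color experiments: on each trial a
participant memorizes 1–4 hues drawn from the HSV color circle, and after
a 2500-ms retention interval reproduces one probed hue on a color wheel
while pupil size is recorded (nominally at 1000 Hz, from 1500 ms before
memory-display onset to 2800 ms after). Target hues are either category
*prototypes* (the central hue of one of seven basic color categories) or
*ambiguous* hues sitting exactly on the boundary between two adjacent
categories. The design crosses memory load (1–4) with color type, 32
trials per cell (256 per participant), with 30 participants as the
reference sample size.

## Category derivation

Categories are derived from a separate hue-categorization dataset in
which every rater labels each of the 360 integer hues once. Steps:

1. **Frequency table** — counts per (hue, label).
2. **Modal label per hue** — ties are resolved in favor of the preceding
   hue's modal label (circularly), preserving single-crossing structure.
3. **Boundaries** — wherever the modal label differs between hues `h` and
   `h+1` (mod 360), a boundary is placed at `h + 0.5`. The midpoint
   convention is symmetric and unbiased; it introduces an irreducible
   0.5° quantization relative to any continuous ground truth. A
   *persistence filter* (default 3 hues, configurable) accepts a label
   change only when the new label stays modal for that many consecutive
   hues, since with noisy raters the modal sequence can flicker around a
   boundary.
4. **Prototypes** — the circular midpoint of each pair of consecutive
   boundaries, along the arc that is the category.
5. **Rater screening** — leave-one-out agreement: each rater's responses
   are compared with the modal labels recomputed from all other raters;
   raters below a configurable agreement threshold (default 0.5) are
   flagged. This is a quantitative surrogate for visual inspection of
   deviant raters, chosen for reproducibility.

## Mixture model of recall errors

Signed circular errors `e ∈ (−180°, 180°]` are modeled as

`p(e) = (1 − g)·VM(e; κ) + g/360`,

a von Mises memory component centered on the target (concentration
κ ∈ [0, 10000], "precision") plus a uniform guessing component with
weight `g ∈ [0, 1]`. The density is expressed per degree and evaluated
with exponentially scaled Bessel functions so it stays finite at the
κ = 10000 bound. Bias toward category prototypes is deliberately *not* a
parameter: the model is the classic two-parameter decomposition, so a
categorical response to an ambiguous target shows up as lower fitted
precision, which is exactly the contrast the analysis exploits.

**Optimization.** κ is searched on a `log(1+κ)` scale (the likelihood is
flat in κ at large κ and boundary-prone at both ends) with L-BFGS-B from
five starting points taken from a 50×50 log-spaced verification grid; the
returned optimum is guaranteed to be at least as good as the best grid
point (the grid maximum is returned, flagged unconverged, if every start
fails). Two identifiability conventions: an error set concentrated at 0
drives κ to its upper bound with g → 0; and because κ = 0 makes the
memory component itself uniform — leaving g undetermined along a ridge of
equal likelihood — such fits are reported as pure guessing (κ = 0,
g = 1). Fits are performed per participant × load × color-type cell (the
granularity the within-subject ANOVA requires), with a configurable
minimum of 10 errors per fit.

## Pupil preprocessing

1. **Blink reconstruction.** Blinks arrive as runs of zero (or missing)
   samples. Runs of at least 20 ms are widened by a 50-ms margin on both
   sides (the signal is distorted just before and after lid closure) and
   bridged by a cubic polynomial through four flanking valid samples, two
   on each side spaced by the margin — the standard pupillometry recipe.
   Sub-threshold dropouts are bridged linearly; runs touching a trace
   edge are filled with the nearest valid value; fully missing traces are
   excluded. Reconstruction is idempotent on clean traces.
2. **Baseline correction.** The mean pupil size during the first 100 ms
   of the memory display is subtracted from the whole trace and stored.
   The first 100 ms of the pre-cue period is available as a control
   baseline window.
3. **Baseline outlier exclusion.** Per participant, trials whose baseline
   z-score exceeds 2 in magnitude (SD with n−1 denominator; two-sided,
   since a deviation in either direction signals an artifact) are
   excluded from the *pupil* analysis only — behavioral analyses always
   see every trial. Under Gaussian baselines this removes ≈ 4.6% of
   trials. Zero within-participant SD produces no exclusions.
4. **Binning.** Half-open windows `[t, t+Δ)` aligned to memory-display
   onset over [0, 2500) ms; each window value is the mean of its samples.
   The analysis default is Δ = 10 ms; scaled-down runs use 50–100 ms.

## Window-wise mixed models

Per window, a linear mixed model of pupil size with fixed effects memory
load (numeric, centered at 2.5), color type (sum-coded: ambiguous = +0.5,
prototypical = −0.5) and their interaction, and by-participant random
intercepts and slopes for all fixed effects. Statistics are large-sample
z = coefficient/SE with normal p-values. A term is *significant* when
p < α = .05 for at least 200 ms of consecutive windows — runs shorter
than the threshold are never clusters.

**Convergence ladder.** If the full random structure fails to converge,
the window is refit with random intercepts only and flagged; if the
random-intercept variance itself collapses to zero (statsmodels then
reports a singular random-effects covariance and unusable standard
errors), the model is refit as OLS — which is exactly what a mixed model
with zero between-participant variance reduces to — and flagged.
Windows unfittable even then are reported with missing statistics, never
silently dropped.

**Cross-validated localization.** Selecting the window where an effect is
strongest and testing it on the same data inflates the statistic. The
anti-circularity procedure: trials are partitioned into four interleaved
folds by within-participant trial rank modulo 4 (balancing session-time
drift across folds); for each fold, the other three folds select the
window maximizing |z| of the interaction; each held-out trial contributes
its pupil value at its fold's winning window; the pooled held-out values
(every trial exactly once) are fit once with the same model, and that
fit's z and p are reported together with the per-fold winning windows.
One window is selected per fold; different folds may disagree, which is
informative about localization stability.

**Follow-ups.** The color-type effect is tested per memory load on each
trial's mean pupil size inside the localized window (spanning the
earliest to latest winning window), with a by-participant random
intercept + color-type slope and the same convergence ladder.

## Behavioral statistics

* **Above-chance check.** Per participant, response hues are shuffled
  across trials (once by default, literal shuffling; pooling over many
  shuffles is available) and a one-sided two-sample t-test compares real
  vs shuffled absolute errors. Under uniform responding the flag rate is
  the nominal one-sided α.
* **RM-ANOVA.** Classical two-way within-subject decomposition (load ×
  color type), each effect tested against its own effect-by-subject
  interaction: dfs (3, 3(n−1)), (1, n−1), (3, 3(n−1)) — (3,87)/(1,29)/
  (3,87) at n = 30. Greenhouse–Geisser epsilons (via orthonormal
  contrasts on the cell covariance) and corrected p-values are reported
  alongside, but the primary columns are uncorrected, matching standard
  reporting practice for this design.
* **Paired follow-ups.** Ambiguous vs prototypical per load,
  `t` with df = n−1; degenerate zero-variance differences are reported as
  t = 0, p = 1 (no shift) or |t| = ∞, p = 0 (constant shift).
* **Response densities.** Descriptive von Mises kernel densities of
  response hues per (target hue, load) on the 1° grid, kernel κ = 50
  (≈ 8° SD) by default; each group integrates to 1.

## The synthetic-data generator

The generator produces all three inputs with controllable ground truth.

* **Categorization**: true category structure (equally spaced boundaries,
  optional Gaussian jitter), each rater labels all 360 hues; with
  probability `label_noise` a response is a uniformly chosen *adjacent*
  category (mislabelings happen at category edges, not across the wheel).
* **Trials**: a response is, with probability `guess_rate_by_load[load]`,
  uniform; otherwise with probability `p_categorical[load, type]` a von
  Mises draw centered on the prototype of the target's category
  (κ_categorical = 8 by default, ≈ 20° SD); otherwise a von Mises draw
  centered on the target (κ_continuous = 50, ≈ 8° SD). For a target on a
  boundary, the categorical encoder picks the upper flanking category
  with probability `ambiguous_bias` (0.5 — a fair coin — by default;
  real data show asymmetric attraction, but no principled rule exists,
  so the bias is a parameter). The default `p_categorical` rises with
  load (0.1/0.4/0.7/0.9) and default guess rates rise from 0.02 to 0.25,
  producing the canonical load effects on precision and guess rate.
* **Pupil**: per trial, baseline (mean 1000 a.u., between-trial SD 50)
  + `load_slope`·load (20 a.u./item) from 500 ms onward + a color-type
  effect added to ambiguous trials inside 1290–2140 ms with amplitude
  +20/+7/−7/−20 a.u. for loads 1–4 (positive = ambiguous larger: the
  sign pattern inverts across load), + AR(1) Gaussian noise (stationary
  SD 50, per-sample autocorrelation 0.9) + Poisson blinks as zero runs
  (1 per trial, 150 ms). AR(1) noise captures the strong temporal
  autocorrelation of pupil data cheaply; blinks as zero runs follow the
  eye-tracker convention. The sample rate is configurable; tests use
  100 Hz, which leaves every effect and every preprocessing step intact
  at a tenth of the data volume.

**What the generator does not emulate:** participant-level heterogeneity
of the load and color-type effects (effects are fixed across
participants), luminance confounds, gaze-position artifacts, slow
session drift, and realistic pupil impulse-response dynamics (effects
are step-shaped). Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated on data with the
designed covariance structure, not that any particular empirical dataset
will show these effects.

## Problem sizes and numerical choices in the validation suite

* Calibration of the cross-validated test uses 200 null simulations at
  10 participants × 8 trials/cell with 100-Hz traces and 100-ms windows;
  localization uses 50 runs at 15 × 24 with 50-ms windows; the headline
  pattern uses the full 30 × 32 design. Scaled-down runs use the
  intercept-only random structure, which is the correctly specified
  model for the generator (whose effects have no participant-level
  variance); the full random-slopes structure remains the analysis
  default and its convergence ladder is exercised separately.
* A winning window "falls inside" an interval when its midpoint does —
  at coarse window widths the window grid need not align with the
  interval's endpoints.
* Cluster detection treats missing (NaN) p-values as non-significant,
  breaking runs.
* The global seed is expanded into independent per-stage streams with
  `numpy.random.SeedSequence.spawn`, so any stage can be rerun
  reproducibly in isolation.

## Known limitations

* Mixed-model p-values are large-sample normal approximations; with very
  few participants they are mildly anticonservative (the CV calibration
  test bounds this empirically at its design size).
* The two-parameter mixture cannot separate "categorical response" from
  "imprecise continuous response"; the pipeline's inference rests on the
  load × color-type *pattern* of fitted precision, not on classifying
  individual responses.
* Boundary placement is quantized to 0.5°; category recovery can never
  beat that resolution.
* The blink reconstruction is a generic cubic-bridge repair; it does not
  model pupil-size dynamics during partial occlusion.
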