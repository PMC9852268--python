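# Methods

This note documents the models and procedures `vfprog` implements, the
defaults it chooses where the field's published descriptions leave the
design open, and what its synthetic-data tests do and do not demonstrate.

## Data model and filters

A series is the date-ordered run of 24-2 exams for one eye: 54 total-
deviation (TD) values in a canonical order (rows top to bottom, within a
row nasal to temporal), global indices (MD, PSD, VFI), reliability indices
(false positives %, false negatives %, fixation losses), date, age and test
duration. Everything downstream runs in right-eye orientation; left-eye
fields live on the mirrored lattice and are permuted on load (the
permutation is an involution, tested as such). Total deviation is used
throughout, never pattern deviation.

Reliability is the study rule: an exam is kept when FP < 15 % and
FN < 25 % (mild/moderate) or FN < 50 % (severe), all strict. The severity
class for the FN cutoff is not defined by the published rule; we stage each
exam by its own MD with a conventional boundary of −12 dB (configurable via
`vfprog.core.SEVERE_MD_CUTOFF`). Eyes enter analysis with ≥ 7 reliable
exams. Baselines for the event-based methods average the first two
*reliable* exams — filtering runs first, a deliberate resolution of an
ambiguity in the usual wording ("the first two VFs").

## The six labelers

Trend methods regress against years since the first included exam (day
resolution) over the whole series — no windowing. Comparison operators
follow the printed rules exactly: strict p < 0.05 for the MD
(≤ −0.5 dB/yr) and VFI (≤ −1.8 %/yr) slopes, inclusive p ≤ 0.01 for PLR
(≥ 3 of 52 points at slope ≤ −1 dB/yr). The per-point PLR regressions are
vectorized closed-form OLS, cross-checked against scipy and a
normal-equations oracle.

Event methods compare follow-ups (exams 3…n) to the two-exam baseline and
require the change criterion on **three consecutive** follow-up fields:

* **GPA-like.** A follow-up qualifies when ≥ 3 seeing points fall below
  their per-point α < 0.05 test–retest change threshold. The published
  procedure took thresholds from an empiric normative database that is not
  redistributable; the `ThresholdTable` is therefore a required, documented
  input, and the default is Monte-Carlo simulated from the cohort noise
  model (5th percentile of follow-up-minus-baseline change in stable eyes;
  for homoscedastic noise sd σ this converges to −1.645·σ·√1.5, which the
  tests verify). The rule does not require the *same* three points across
  the window; a stricter same-points mode is available
  (`gpa_flag(..., same_points=True)`).
* **AGIS.** Integer score 0–20 = nasal (0–2) + superior (0–9) + inferior
  (0–9) components from counts and depths of contiguous depressed sites.
  Sector membership (6 nasal / 23 upper / 23 lower sites), count bins
  (3–5 / 6–12 / 13–20 / > 20) and depth increments (≥ 12/16/20/24/28 dB for
  at least half the depressed sites) follow the published trial structure;
  the per-site depth cutoffs in `vfprog/data/agis_tables.json` (v1) are an
  eccentricity-based approximation (5–9 dB) of the trial's site map, since
  the original table is not reproduced in our sources. The file is
  versioned and replaceable; the code validates only the structural caps,
  so verbatim trial tables can be dropped in. Worsening = score increase
  ≥ 4 sustained on 3 consecutive follow-ups.
* **CIGTS.** Each seeing point gets a defect level 0–4 from per-point TD
  percentile cutoffs (p < 5/2/1/0.5 %); its weight is the minimum of its
  own level and the two highest levels among its immediate neighbors
  (8-neighborhood at 6° spacing, midline-crossing allowed by default,
  configurable), so isolated defects weigh zero; score = Σweights / 10.4
  ∈ [0, 20]. Worsening = increase ≥ 3 sustained on 3 consecutive
  follow-ups. Default cutoffs are the normal-eye noise-model quantiles.

## Consensus and agreement

The reference standard is k-of-6 with k = 4 (parameterized;
`consensus_prevalence_by_k` reports the k = 1…6 sensitivity curve). With
k = 4, any worsening call necessarily includes one event- and one
trend-based method — asserted by exhaustive enumeration of all 64 flag
vectors. Clinician chart choices map {likely, possible worsening} →
worsening before any agreement computation.

Cohen κ uses the standard large-sample SE; the CI method is a package
choice, as is the seeded eye-level bootstrap for the Fleiss κ CI (the
published analyses name no interval method). Degenerate marginals yield an
explicit "undefined" result, never a silent zero. Verbal bands follow the
0.2/0.4/0.6/0.8 convention.

## Synthetic cohorts

The generator is a testing stand-in, not a physiologic simulator. Defaults
are the target population's marginals: 11.9 ± 4.59 reliable exams/eye
(floored at 7; the latent normal mean is solved numerically so the floored
mean still equals 11.9 — the floored SD is then slightly below 4.59, an
accepted consequence), spacing 1.04 ± 0.37 yr, age 62 ± 12, initial MD
−2.51 ± 3.86 dB, global slope −0.17 ± 0.42 dB/yr, 71 % of patients
contributing both eyes (fellow eyes share the baseline field shape plus
independent perturbation). A configurable fraction of eyes (default 0.15)
additionally loses a contiguous same-hemifield cluster of 6 points at an
extra −1.5 ± 0.4 dB/yr — the injected ground truth.

Test–retest noise is heteroscedastic: per-point sd = 1.2 dB + 0.2 ×
defect depth (dB), the magnitude range reported for damaged field
locations, and the property that makes event-based criteria nontrivial.
Global indices are documented surrogates, **not** Humphrey formulas: MD =
unweighted mean of the 52 seeing TDs, VFI = 100·(1 − mean defect
depth/30) clipped to [0, 100], PSD = TD standard deviation. They preserve
the monotone relationships the labelers need but not instrument scaling.
Reliability indices are drawn near the population marginals with 5 % of
exams made deliberately unreliable to exercise the filters; the simulated
clinician reads the truth as a Bernoulli with TPR 0.42 / FPR 0.16.

What the generator does **not** emulate: retinal-nerve-fiber-bundle
scotoma geometry, SITA staircase behavior, learning/fatigue effects,
floor effects at low sensitivity, or correlated (non-Gaussian) test–retest
noise. Passing pipeline tests therefore demonstrates internal consistency
of the methods under a plausible noise model, not clinical performance.
One visible consequence: with deep baseline defects and a single per-point
threshold table, the GPA-like labeler flags aggressively in damaged eyes —
the known behavior of pointwise change criteria without baseline-
stratified limits.

## Classifier and baseline

Rasterization deposits each seeing point into a 12 × 12, 5°-cell lattice
covering ±30° and smooths with a weight-normalized Gaussian kernel (radius
1 cell, σ 0.8 cells — configurable); untouched cells keep the fill value
(0 dB). The 8 global metrics (z-scored on the training set) and the
inter-exam spacing (Δt, years) are broadcast over the grid as extra input
channels — chosen over a separate recurrent branch to keep the published
single-layer architecture; the fusion is isolated in
`_Normalizer.input_tensor`. The network is one 2-D convolutional LSTM
(3 × 3 kernel, 8 hidden channels, forget-gate bias +1), final-time-step
hidden state global-average-pooled, batch-normalized, dense sigmoid head.
Training: Adam (lr 10⁻², batch 32 of equal-length sequences), binary
cross-entropy, early stopping on validation loss (patience 6); weight init
and shuffling flow from one seed, so fits reproduce exactly
single-threaded. The unstated optimizer/loss/learning-rate choices are
fixed defaults recorded here. Automatic differentiation is a small
reverse-mode engine over numpy arrays shipped with the package and pinned
by finite-difference tests.

Splits are patient-level 80/10/10 with fellow eyes co-assigned (hard
assertion at partition time). The ablation drops the final r ∈ 1…6 exams
from every series (each eye keeps ≥ 1 exam), retrains per r, and keeps the
full-series consensus label.

The mixed-effects baseline is a logistic model on per-exam rows — the 8
metrics, Δt, and two raster summaries (mean and minimum) as fixed effects;
patient and eye as crossed random intercepts — fitted by variational Bayes
(statsmodels `BinomialBayesMixedGLM`, sparse random-effect design,
L-BFGS-B capped at 300 iterations). Since the posterior random effect of
an unseen eye is zero, test eyes are scored by the eye-mean fixed-effect
linear predictor; temporal structure reaches this model only through
per-row covariates, which is exactly why a recurrent model can beat it.

## Evaluation

AUC is trapezoidal with a seeded eye-level bootstrap CI (2000 replicates
by default; the published CI method is unstated). Clopper–Pearson
intervals come from beta quantiles. Severity strata cut initial MD at
−6 dB (parameterized). For a single-operating-point rater the minmax
construction assumes a monotone concave ROC: the point estimate (= lower
bound) is the polyline area through (FPR, TPR); the upper bound extends
the origin chord to TPR = 1 (area 1 − FPR/(2·TPR)). Below-chance points
are reported as-is with a warning, never mirrored. At (FPR 0.16,
TPR 0.42) the estimate is 0.63.

## Problem sizes in the shipped tests

The full-pipeline test cohort uses 360 patients (~620 eyes, seed 11),
normative thresholds from 5000 Monte-Carlo replicates, a 20-epoch
convLSTM (hidden width 8) and ablation at r ∈ {0, 3, 6}; the moment and
recovery tests use 500- and 140-patient cohorts. These sizes are the
package's choice for a fast, deterministic test suite; all pipeline
assertions are ordinal (separations, orderings, trends), not point
reproductions.

## Known limitations

* AGIS per-site depth cutoffs and the CIGTS probability cutoffs are
  config approximations, not the trial tables; both are versioned inputs.
* The VFI/PSD surrogates make VFI-slope behavior a scaled proxy of MD
  slope rather than an independent index.
* The minmax upper bound is the generic concave envelope; tighter bounds
  require distributional assumptions we do not make.
* Fleiss κ CI is a nonparametric bootstrap over eyes; for very small
  cohorts the interval can be wide and asymmetric.
* The mixed-effects VB posterior is approximate; its variance-component
  estimates should not be interpreted, only its ranking of eyes.
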