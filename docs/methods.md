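# Methods

## The task and what the pipeline estimates

In a saccadic-choice trial a fixation cross (800–1600 ms, uniform) is
followed by a 200 ms blank and then 400 ms of two stimuli centered
8.6° left and right of fixation (14° × 14° images). The subject
saccades to the target category. Three categories (familiar faces,
unknown faces, objects) give six ordered target/distractor tasks, one
per block; each block crosses all 9 target images with all 9
distractor images in both hemifields (162 trials), so each image
serves as target 18 times per block and a 7-subject session has 6804
trials.

Two quantities are of scientific interest per task: **choice
accuracy** (did the first saccade go to the target hemifield?) and the
**minimum reliably accurate SRT** — the earliest latency at which
correct saccades significantly outnumber incorrect ones.

## Synthetic gaze generation

The generator's defaults are the study conditions; everything is a
dataclass parameter.

* **Latency.** Shifted log-normal, `SRT = 80 + LogNormal(μ, σ)` with
  σ = 0.30 and μ set so the mean matches the task's condition mean
  (per-task defaults 171–216 ms, taken from the published
  condition-summary table). The 80 ms shift matches the anticipation
  cutoff: genuinely stimulus-driven saccades do not occur earlier.
  Samples are capped at 340 ms so the saccade completes inside the
  400 ms window. A truncated normal is provided as an alternative.
* **Errors.** Either a constant per-task error probability (defaults
  are the published accuracies, 55.3–92.8%) or a latency-dependent
  logistic rise from chance to an asymptote around a crossover
  latency, which is what real saccadic-choice data look like and what
  the minimum-SRT estimator is designed to detect.
* **Kinematics.** The saccade is a normalized logistic displacement
  profile in x (steepness 10), amplitude equal to the 8.6° image
  eccentricity, duration from a main-sequence rule
  (2.2 ms/deg + 21 ms, clamped to 30–60 ms). The profile is smooth,
  monotone, and has a single terminal run of constant velocity sign —
  the property the detector's onset rule relies on.
* **Fixation jitter.** A stationary AR(1) (discretized
  Ornstein–Uhlenbeck) drift with positional SD 0.15° and
  autocorrelation 0.98 per ms. The positional dispersion is the
  conventional fixation-stability figure; the autocorrelation keeps
  sample-to-sample velocity far below saccadic speeds, as in real
  drift. White per-sample jitter of the same positional SD would
  imply ~200°/s fixation "velocity", which no tracker records.
  Optional white measurement noise can be added on top (default 0).
* **Artifacts.** 3% anticipatory saccades (onset uniform 20–75 ms,
  random direction) and 3% fixation breaks (a 3° vertical excursion
  inside the first 80 ms), together mirroring the ~6% rejection rate
  typical of this paradigm. A no-saccade probability exists (default
  0).
* **Geometry.** 800 × 600 px at 50 cm. The physical pixel pitch is
  not derivable from these numbers, so `px_per_deg` is a free
  parameter defaulting to 25 px/deg, which places the outer stimulus
  edge (15.6°) just inside the half-screen width. The inner image
  border used by the detector is 8.6 − 7 = 1.6° from center.

What the generator does *not* emulate: blinks, pupil dynamics,
vertical or curved saccades, calibration drift, main-sequence
variability across saccades, and post-saccadic oscillations. Passing
recovery tests therefore show the algorithms are correct under the
stated model, not that they are robust to every artifact of real
recordings.

## Saccade detection

Velocity is the 2-D point-to-point speed at 1 ms steps, aligned to the
later sample. The threshold is 3 × SD of the velocity over the 200 ms
pre-stimulus blank — the SD is taken about the baseline mean, reading
"three standard deviations of the velocity" as a dispersion
criterion. Direction comes first: the earliest post-onset sample at or
beyond an inner image border fixes left/right. Candidate onsets are
supra-threshold samples between stimulus onset and the crossing; the
onset is the start of the terminal run of constant horizontal-velocity
sign ending at the crossing (the last sign change), provided that run
contains at least one candidate. If the trace is monotone from
stimulus onset the rule's "last sign change" is undefined and the
first candidate is used; if the terminal run contains no candidate the
crossing was not produced by a saccade-speed movement and no onset is
returned. Anchoring the onset at the sign change rather than at the
first supra-threshold sample avoids the systematic late bias that the
threshold alone would introduce while the saccade is still
accelerating.

Rejection filters, in order of precedence: anticipation (onset
< 80 ms; exactly 80 ms is accepted — "before" is read left-open),
fixation failure (any sample within 2° default radius violation in the
first 80 ms after stimulus onset), missing saccade. Traces with
non-finite samples in the analysis window are rejected with a logged
reason, since the rule is undefined on gaps.

## Minimum-SRT estimation

Bins are 10 ms wide and left-inclusive: the bin centered at `c` covers
`[c − 5, c + 5)`, so 115–124 ms is the 120 ms bin. Per bin, the
chi-square goodness-of-fit statistic of (correct, incorrect) counts
against equal expectation is compared with 2000 Monte Carlo binomial
replications; the p-value uses the add-one estimator
`(1 + #{sim ≥ obs}) / (B + 1)`, which can never be zero. A bin is
*significant* only when `p < .05` **and** correct > incorrect — the
chi-square alone is two-sided and would otherwise count significantly
wrong bins. Scanning ascends from the 80 ms bin (the acceptance floor)
to the last bin with data; empty bins are non-significant and break
runs. The minimum SRT is the first bin of the first run of ≥ 5
consecutive significant bins ("five such consecutive bins" is read as
at-least-five). Condition summaries report accuracy and mean SRT per
task × hemifield; mean SRT uses correct trials only (the same
convention as the latency model) and is suppressed for tasks whose
accuracy the inference stage cannot distinguish from chance.

## Mixed-effects inference

Fixed effects in both models: Task, TargetPosition, their interaction,
and the trial number z-scored within the data set (z-scoring rather
than centering alone, to keep the design well-conditioned; the exact
scaling convention is otherwise immaterial to the tests reported).

**Random-effect selection.** Two candidate random-intercept
structures: fully crossed (subject + target item + distractor item)
and subject-combination (subject + subject:target + subject:
distractor). Both have three variance parameters, so the ML
log-likelihoods are directly comparable and the higher one wins (first
candidate on exact ties). Each retained effect must then survive a
likelihood-ratio test of the model without it against the full model,
at the naive chi-square(1) reference to match common reporting
practice; the 50:50 chi-square(0)/chi-square(1) boundary mixture is
available via `boundary_mixture=True`.

**Fixed-effect tests.** Type III Wald chi-square per term under
sum-to-zero contrasts (each term tested in the presence of all
others) — the statistic produced by `car::Anova` on mixed models,
which is the convention this workflow mirrors. An LRT variant can be
assembled from the exposed fits.

**Estimates.** The model is refit without intercept: cell-means coding
for Task with TargetPosition treatment-coded against a reference
hemifield, so each Task coefficient is that task's log-odds (or log
latency) in the reference hemifield, directly contrasted against 0 =
chance for the logit model. Refitting with the other reference level
yields the other hemifield's estimates; the likelihood is invariant to
the reparameterization (checked to optimizer tolerance). A task is
declared above chance when its 95% bootstrap interval excludes 0 in
both hemifields. The latency model uses correct trials only, excludes
chance-level tasks, fits ML for comparisons and REML for final
estimates, and reports estimates both on the log scale and
exponentiated to ms (task cells) or ratio (contrast) scale.

**Parametric bootstrap.** Responses are simulated from the fitted
parameters (new random effects and residuals each draw), the model is
refit warm-started at the fitted variance parameters, and percentile
95% intervals are taken per parameter; 10,000 draws for release runs,
reduced sizes in the test suite. Refit failures are dropped; more than
10% failing is an error.

**Fitters.** The models themselves are fit by a compact in-package
implementation (`sacchoice.glmm`): the Gaussian model by the profiled
ML/REML deviance over relative random-effect SDs, solved through the
q × q penalized least-squares system; the Bernoulli-logit model by a
Laplace approximation with joint Newton optimization of fixed effects
and conditional modes and a derivative-free outer loop over the
variance parameters (equivalent to lme4's fast joint-mode scheme,
`nAGQ=0`). Writing the fitter in-package keeps a bootstrap refit in
the millisecond range, which the coverage simulations require; its
output is cross-checked in the test suite against statsmodels
``MixedLM`` (Gaussian, exact REML likelihood agreement) and against
``lme4::glmer`` via Rscript (logit, agreement to ~1e-3 on a fixture).
Only random intercepts are supported, which covers every structure the
workflow uses. Warm-started bootstrap refits may use coarsened outer
tolerances (`coarse=True`); percentile intervals of fixed effects are
insensitive to the last digits of the variance parameters.

## Numerical and design choices

* Degenerate inputs: zero-variance images warn and return the target
  mean; empty latency bins return p = 1 with a warning; non-positive
  SRTs make the log-latency model raise; complete separation (a cell
  at 0% or 100% accuracy) triggers a warning since the log-odds is
  unbounded.
* Ties and boundaries: onset exactly at the 80 ms cutoff is accepted;
  bin edges are half-open; equal-likelihood random-structure
  candidates resolve to the first listed; variance parameters are
  optimized on `|θ|` so the boundary θ = 0 is reachable.
* Problem sizes in the test suite: onset recovery uses a 500-trial
  battery; estimator operating characteristics use 100 replicates at
  800–900 trials; bootstrap coverage uses 300 replicates of a
  200-observation model at 500 draws; the workflow tests use 1–5 k
  trial experiments with 80–300 bootstrap draws. These sizes give
  Monte Carlo error comfortably below the asserted margins while
  keeping the default `pytest` run desk-scale.

## Known limitations

* The logit fitter's Laplace/joint-mode likelihood differs slightly
  from adaptive-quadrature fits (lme4's default `nAGQ=1`); for the
  balanced designs here the difference is in the third decimal of the
  fixed effects.
* The onset rule presumes a single decisive saccade; staircase double
  saccades within the window resolve to the final sweep.
* Percentile bootstrap intervals are first-order; no BCa correction.
* The no-intercept "above chance" criterion requires the interval to
  exclude zero in both hemifields, which is conservative for tasks
  with hemifield asymmetries.
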