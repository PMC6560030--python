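# Methods

## The analysis this package implements

The package re-implements, at region-of-interest (ROI) level, a
multivariate analysis pipeline for detecting *prospective* state
representations during goal-directed learning. The task is a Y-maze
paradigm: on each trial the participant sees a maze-unique picture in a
choice room (state 1, S1), picks a left/right door, passes a hallway room
(S2) and a pre-outcome room (S3, again with a maze-unique picture), and
receives reward or loss feedback ~40 s after the choice, followed by a
12-s rest period. Eight mazes of interest are repeated four times (plus
two extra always-losing mazes), in four scanning blocks of ten trials;
each maze assigns the three stimulus categories — face, scene, object —
one each to S1, the correct S3, and the incorrect S3. A post-learning
localizer phase (155 trials: 120 category trials in three mini-blocks of
40, 20 scrambled-object and 15 motion trials) provides independent
training data for category classifiers.

The inference chain is:

1. **Single-event (LSA) GLM.** Every event of every state, including
   rest, gets its own boxcar regressor (durations 5 s for S1/S3/feedback,
   4 s for S2, 12 s for rest; 2 s/3 s for static/motion localizer trials)
   convolved with the canonical double-gamma HRF at TR = 1.24 s, plus
   block intercepts and six motion-like nuisance columns. Forty trials x
   five states = 200 regressors of interest. Ordinary least squares gives
   one beta pattern per event.
2. **Cross-phase pairwise classification.** Three linear SVMs (LIBSVM
   behaviour, fixed cost c = 1) are trained on localizer betas — faces vs
   scenes, scenes vs faces, objects vs faces — with class counts equalized
   per mini-block by seeded discard. They are *applied*, never retrained,
   to learning-phase betas. Margins are mapped to decision values in
   [0, 1] by a one-parameter symmetric logistic link fitted on localizer
   margins with Platt's smoothed targets; a pattern on the decision
   boundary maps to exactly 0.5 and the map is strictly increasing, so
   decision values carry the margins' rank order.
3. **Decision-value regressions.** Per category, S1 decision values from
   the eight mazes of interest are regressed on: a binary current-state
   indicator, a binary future-state indicator (the category of the
   *correct* arm's S3), the correct-repetition counter r (0 until the
   repetition after the correct S3 was first observed, then +1 per
   repetition), and the two interactions. The future x r interaction is
   the critical quantity: evidence that the distal category's
   representation grows with experience of it. Coefficients are averaged
   over the participant's valid categories; group inference is a
   one-sample two-sided t test. Categories whose classifier fails to
   generalize across phases (non-positive regression of concatenated
   S1+S3 decision values on the target-vs-contrast indicator) are
   excluded; a participant is dropped only if all three fail.
4. **Controls.** Per-bin models (current and future effects estimated
   separately at each value of r), reduced models (current or future
   terms removed), state-variant models at S2/S3/feedback, and a
   multi-ROI sweep reported with uncorrected p values.
5. **Univariate models.** A decaying-encoding parametric modulator with
   geometric 50% decay — values 1, 0.50, 0.25, 0.125 over the four
   repetitions — at S1 (optionally S2/S3), and a +1/−1 reward/loss
   contrast at feedback, optionally extended through rest. The modulator
   is mean-centered before entering the design (SPM convention). No
   joint value + decay model is offered: with fixed reward contingencies
   the two are strongly collinear by construction.
6. **Equivalence and power.** One-sample TOST with symmetric bounds in
   Cohen's d (converted to raw units by the sample SD; p = max of the two
   one-sided p values), plus calculators for the minimum n of a
   one-sample t test and for the TOST bound attaining a target power,
   both using the noncentral-t distribution (integer search /
   root-finding). These reproduce the conventional printed values n = 38
   (d = 0.47, 80% power, two-tailed), n = 30 (one-tailed), and bound
   d = 0.53 at n = 32. For n = 29 the noncentral-t root is d = 0.557
   (0.56 at two decimals); an exact joint Monte-Carlo of the two
   one-sided tests confirms the root to three decimals, so conventions
   that print 0.55 for this case appear to use a slightly different
   approximation.
7. **Learning PPI (simplified).** Seed-to-target connectivity change is
   indexed by the coefficient of (centered seed timecourse) x
   (HRF-convolved late-minus-early contrast), with both main effects in
   the model. Late = correct-repetition bins 2–3, early = bins 0–1
   (0-indexed), zero-sum weights, unlearned mazes omitted. No BOLD
   deconvolution is attempted — a stated simplification relative to
   SPM-style PPI. At the group level the interaction coefficients are
   tested against zero and correlated with each participant's
   future x r decoding effect.

## The synthetic-data generator

The generator produces the full design (maze specs, staged trial order,
timed events, localizer list), behavior, and voxel patterns with known
ground truth, so the whole chain can be validated by parameter recovery.

**Behavior** follows a two-parameter observe-then-exploit rule. The first
choice is random; its outcome is forced by the design (exactly half the
mazes of interest reward the first exposure, so repetition-1 accuracy is
50% by construction). From repetition 2 the correct door is chosen with
probability `p_learn_after_reward` = 0.821 once the correct S3 room has
been observed and `p_learn_after_loss` = 0.714 before then. The defaults
are the observed conditional second-repetition accuracies (82.1% after an
initial reward, 71.4% after a loss; 76.8% overall), and produce a rising
learning curve because initially-lossy mazes graduate to the higher rate
once learned.

**Patterns** are built from orthonormal category templates T(c) (QR of a
seeded Gaussian matrix, so templates cannot be confounded):

* localizer category trial: `a_localizer * T(c) + noise`
* S1 event: `a_current * T(on-screen) + g_future * r * T(correct-S3) + noise`
* S3 event: `a_current * T(visited arm) + noise` (optional repetition
  slope for suppression analyses)
* S2 / feedback / rest: optional planted terms (zero by default) + noise

Noise is iid Gaussian per voxel. The future signal is planted *linearly*
in r, matching the linear interaction the analysis fits (a square-root
growth option exists). Defaults: 64 voxels, `a_localizer` = 1.0,
`a_current` = 0.6, `g_future` = 0.15, `noise_sd` = 0.5. These were fixed
once by a design-time power analysis of the generative model: they give a
group-level future x r effect of Cohen's d ≈ 0.7 in a 30-participant
cohort (roughly 95% power — a well-powered replication of a
medium-effect finding), while keeping the future signal subordinate to
the on-screen signal (maximum planted future amplitude 0.45 < 0.6 at
r = 3), so on-screen classification, the AUC generalization check, and
the exclusion rule all behave as they must. Localizer decoding is nearly
perfect at these settings and learning-phase cross-classification is
reliable but far from ceiling. Setting `g_future = 0` yields a null
world in which current-state decoding persists while the future
interaction is centred on zero — the double dissociation the design
relies on.

**Timing.** Inter-state hallway gaps are uniform jitters chosen so the
mean S1-to-S3 interval is ~31 s and the mean maze duration ~48.5 s (the
paradigm's means); exact jitter distributions are not part of the
published design and are therefore approximate. A compact-timing option
shrinks the gaps for BOLD-level demonstrations.

**BOLD forward model.** Boxcars at the modeled durations convolved with
the canonical double-gamma HRF (via nilearn's `spm_hrf`) on a 16-bin
microtime grid, scaled by per-event voxel amplitudes, plus optional
linear/cosine drifts and white noise. Noiseless forward simulation
followed by LSA inversion recovers planted amplitudes to better than
1e-6 relative error.

**What the generator does not emulate:** autocorrelated (AR) scanner
noise, motion artifacts and their correction, spatial structure across
voxels, hemodynamic variability across regions, attention or strategy
shifts, and any image-level stimulus properties. Passing recovery tests
therefore validates the *statistical machinery* — that the pipeline
estimates what it claims to estimate when its assumptions hold — not the
pipeline's robustness to real scanner physics.

## Numerical choices

* OLS throughout (`numpy.linalg.lstsq`); the AR(1) prewhitening used with
  real scanner noise is out of scope, but `fit_betas` accepts a whitening
  matrix for users who need it. Rank-deficient designs fail loudly,
  naming the collinear columns.
* Predictors are left uncentered (binary 0/1, counts 0–3); a centering
  option exists and affects only main-effect interpretation, not the
  interactions.
* The margin-to-decision-value link is `sigmoid(a * margin)` with a > 0
  fitted by maximum likelihood using Platt's smoothed targets
  ((n+1)/(n+2) and 1/(n+2)); without smoothing, separable training
  margins push a to infinity and the values saturate at exactly 0/1.
* AUC is reported chance-relative as (AUC − 0.5) x 100 to match the
  printed scale of ROI generalization values (e.g. "9.88" for an AUC of
  0.5988); the raw AUC is available via `scale=False`. This scaling is an
  interpretation, flagged as such.
* Cross-phase generalization for exclusion concatenates S1 and S3 events
  ("both" states jointly); the future-state indicator uses the correct
  arm's category regardless of the arm actually visited (the
  experienced-arm alternative is exposed as an option). Both points are
  ambiguous in the source description; the chosen readings are the ones
  that keep the covariate well-defined on error trials.
* Degenerate inputs are flagged, not silently propagated: zero-variance
  samples return NaN t statistics with a note; per-bin models skip bins
  whose two indicators are collinear; a category whose interaction column
  is identically zero (maze never learned) is marked invalid rather than
  crashing the cohort.
* Power search starts at n = 2 (df = 1). Note that at df = 1 the
  one-sample t test's power saturates near 0.73 for any effect size, so
  requests for 80% power return n = 3 even for enormous effects.
* All randomness flows from one master seed through named SHA-256-derived
  substreams per stage and participant; identical configurations are
  bit-reproducible.

## Problem sizes used by the test suite

Unit tests use single participants or constructed designs. The
parameter-recovery suite runs 100 cohort replications of 30 synthetic
participants each in the signal world (detection rate required ≥ 90%) and
100 in the null world (type-I rate compared against its binomial band;
TOST at the n-matched 80% bound expected to declare equivalence in ~80%
of cohorts, again within a 3-sigma binomial band). Monte-Carlo
cross-checks of the power calculators use 10,000 replications.

## Known limitations

* ROI-level only: no voxelwise whole-brain inference, smoothing, or
  cluster correction, and no searchlight.
* The PPI is the simplified product form; deconvolution-based PPI will
  differ quantitatively.
* The behavioral rule is a stand-in with the right conditional means and
  learning curve, not a fitted cognitive model.
* Real-data effect sizes (classification AUCs, regression coefficients)
  depend on scanner noise structure and ROI choice and are not expected
  to match the synthetic-world values quantitatively.
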