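# Methods

`expectprofile` simulates and analyzes cue-based expectation experiments in
orientation space: an auditory tone predicts the orientation of an upcoming
grating, and the question is how that expectation reshapes discrimination
performance across the feature distance between the expected and shown
orientations — a flat gradient, a monotonic fall-off, or a center-surround
profile (enhancement at the expected orientation, suppression nearby,
recovery far away).

## Experimental designs

Three paradigms share one cueing structure (orientations 20–70 deg in 10-deg
steps; anchors 20 and 70 deg; low/high tone counterbalanced onto the
anchors):

* **Profile experiment** (orientation task OD, spatial-frequency task SFD):
  baseline phase with uninformative cues (each of 6 orientations at
  validity 1/6 per tone) and a main phase where each tone predicts its
  anchor at 75% validity, the remaining 25% split equally (6.25%) over the
  four non-predicted orientations; the other anchor is never shown under a
  given cue.  Thresholds come from 40-trial adaptive staircases: 2 per
  (anchor condition, orientation) in baseline; 24 at the expected
  orientation and 2 per unexpected orientation in the main phase (the 24:2
  staircase ratio reproduces the 75%/6.25% trial mix exactly).
* **Adjustment experiment**: first grating at {20, 40, 50, 70} deg; the
  participant rotates a probe to match it; the signed error (period
  180 deg, wrapped to [-90, 90)) is the datum.  8 blocks x 48 trials
  baseline, 16 x 48 main.
* **Fixed-offset discrimination**: first grating at {20, 45, 70} deg,
  second offset by +-{1,3,5,7,9} deg; 2AFC clockwise/counterclockwise.
  10 x 120 baseline and 20 x 160 main trials.

## Synthetic observers

Each simulated participant bundles generative parameters:

* **2AFC tasks** — proportion correct at stimulus difference x is
  `guess + (1 - guess - lapse) W(x; DT, beta)`, a Weibull with guess 0.5,
  lapse 0.01, slope beta 3.5, scaled so performance at x = DT is exactly
  75%.  Baseline DT defaults: 3.0 deg (OD), 0.12 cycles/deg (SFD), with
  15% lognormal between-participant variation.
* **DS profile** — the main-phase threshold is `DT_baseline - DS(d)` at
  cue distance d.  The default truth is a Mexican hat (negative second
  derivative of a Gaussian) with peak 0.8 deg and width m = 20/sqrt(3), so
  the surround minimum falls at d = 20 deg — the center of the inhibitory
  zone the profile experiments are designed to detect.  Gaussian
  (monotonic) and flat (null) truths are available for power and
  false-positive calibration studies.  The SFD observer shares the
  orientation-space profile, scaled into cycles/deg by the ratio of
  baseline thresholds, so the profile is independent of the task relevance
  of orientation by construction.
* **Adjustment errors** — drawn from `(1-g) VonMises(mu, sd) + g Uniform`
  in doubled-angle circular space (error_deg * pi/90).  Baseline truth:
  mu 0, sd 8 deg, g 0.05.  Main-phase truth: unexpected-orientation
  representations attracted 0.75 deg toward the expected orientation, the
  expected orientation encoded with s.d. reduced by 0.97 deg; guessing and
  all other deltas 0.
* **Fixed-offset responses** — P(clockwise) = cumulative Gaussian with a
  symmetric 1% lapse; baseline sigma 3 deg.  Main-phase truth: the slope at
  the expected orientation increases by 0.025/deg (sigma tightens
  accordingly); at the unexpected orientation the PSE moves 0.7 deg toward
  the expected orientation.  PSEs live on an "expectward" axis (negative =
  attracted toward the expected orientation), which is how the two anchor
  conditions are pooled.
* **Tone report** — a fixed 90% accuracy Bernoulli, identical across
  conditions, so tone-report accuracy is indistinguishable across distances
  by construction.

Seeding: one `numpy.random.SeedSequence` child per participant; every
stochastic draw derives from it, so runs are bit-reproducible.

## QUEST staircase

The staircase holds a posterior over the threshold in dB-like units
(20 log10 of the stimulus difference) on a +-10 dB grid at 0.02 grain
centered on the prior mean, with a weak Gaussian prior (6 dB s.d.) centered
on the observer's baseline threshold.  The likelihood is the same Weibull
family the observer uses.  Placement and the final estimate are both the
posterior mean (mean-placement QUEST), reported in stimulus units.  The
bounded grid caps the damage an early run of lapses can do; measured over
replicate 40-trial staircases the estimate is unbiased with a coefficient of
variation of ~0.12, which is also the noise level used by the *fast
threshold mode* (Gaussian noise around the generative DT) for large
calibration studies where trial-level simulation adds nothing —
for example the 1000-cohort null calibration.

## Sensitivity profiles and shape comparison

DS = DT_baseline - DT_main per distance {0,10,20,30,40} deg, with the two
anchor conditions pooled by averaging.  Two 3-parameter shapes are fit by
bounded least squares (32 seeded Latin-hypercube multi-starts plus a
moment-based start; widths in (0.1, 200]):

* Gaussian: `y = y0 + 2A/(w sqrt(2 pi)) exp(-2 (x/w)^2)` — one width
  parameter appears in both the normalizer and the exponent.
* Mexican hat: `y = 2H/(sqrt(3m) pi^(1/4)) exp(-x^2/(2m^2))(1 - x^2/m^2) + y1`,
  zero crossings at |x| = m, surround minimum at sqrt(3) m.

Comparison uses AICc and BIC under normal errors
(`AICc = N ln(RSS/N) + 2K + 2K(K+1)/(N-K-1)`, `BIC = N ln(RSS/N) + K ln N`)
and the evidence ratios `LR = exp((AICc_G - AICc_M)/2)`,
`BF = exp((BIC_G - BIC_M)/2)`; values above 1 favor the Mexican hat.  Exact
(zero-residual) fits floor RSS at 1e-300 before the log.  Group-level
ratios use the group-mean DS; per-participant fits use the same routine and
feed the favored-model tally.  Post-hoc paired t tests are reported
uncorrected, and the 5-level repeated-measures ANOVA is reported without
sphericity correction.

## Channel models

Negated thresholds are linearly interpolated onto a 1-deg grid — 61 points
(15–75 deg) for baseline conditions, 51 points (15–65 or 25–75 deg) for the
two main conditions — with the terminal segments linearly extended into the
5-deg margins (nearest-value extension behind a flag).  Channels are
Gaussians `f(x) = A exp(-(x-x0)^2/sigma^2)` on a 10-deg lattice, 6 channels
for baseline and 5 for main profiles:

* **Sharpening**: centers fixed; free per-channel widths plus one shared
  signed energy E with A_i = E/(sigma_i sqrt(pi)), so equal response energy
  holds exactly.  E (and the optional additive offset) enters linearly and
  is profiled out in closed form, so the optimizer searches widths only.
* **Shift**: shared (A, sigma); free centers bounded within +-5 deg of the
  condition's tested range (15–75 baseline, 15–65 / 25–75 main); the shared
  amplitude is profiled out linearly.
* **Combined**: the expected-orientation channel sharpens (free width,
  equal-energy amplitude coupling) while the unexpected channels shift
  (free centers, shared A and sigma), jointly fit to the main profile.

Widths are bounded to [0.01, 200].  Fit quality is RMSD =
sqrt(SSE/(N-K)), penalizing parameter count.  Channel fits default to 12
seeded multi-starts (plus the nominal-lattice start); on the toy problems
where an exhaustive grid search is feasible the optimizer matches it within
1%, and raising the start count does not change the optimum on
profile-scale problems, so the heavier 32-start protocol is reserved for
the (cheap) shape fits.

Phase changes are matched by nominal channel center; the baseline channel
with no main-phase counterpart is dropped.  Because profiles are
negative-valued, a stronger channel response is a more negative A, so the
amplitude delta is reported as response-strength change
`|A_main| - |A_baseline|`.  Location deltas pool with the study's sign
convention: shifts toward 20 deg negative, toward 70 deg positive, mean
shift = (shift toward 70 - shift toward 20)/2.

**Known limitations.**  The equal-energy bank without an offset is weakly
identified on near-flat profiles: widths can grow toward the bound so the
bank's sum absorbs the profile's DC level, and per-participant width and
amplitude changes estimated from full threshold-pipeline data are
correspondingly noisy (the analysis driver prints an offset-variant
sensitivity next to the default).  Relatedly, when the generative truth is
a DS profile rather than an actual channel bank, the shift fit can move
channels *away* from the expected orientation: fitted amplitudes are
negative for negated-threshold profiles, so a response peak is produced by
channel scarcity rather than proximity.  The sign-pattern and recovery
properties the tests assert therefore use channel-bank-generated cohorts,
where both models recover their own generative parameters robustly; what
passing tests show about real data is that the fitting machinery is
correct, not that channel parameters from arbitrary profiles admit the
neural reading.

## Mixture model for adjustment errors

Errors are doubled into circular space and fit by maximum likelihood with
`p(theta) = (1-g) VM(theta; mu, k) + g/(2 pi)`, VM the von Mises density
`exp(k cos(theta-mu)) / (2 pi I0(k))` (computed with the exponentially
scaled Bessel function for stability).  Reported parameters: mu in
orientation degrees, s.d. = sqrt(1/k) converted to degrees, and g.
Optimization is L-BFGS-B over (mu, log k, g) with g in [0,1] and k in
[1e-4, 500], refined from the best 3 points of a (mu, k, g) lattice scan
(mu in {-60..60} by 20 deg, k in {0.5, 2, 8, 32}, g in {0.05, 0.3}); the
returned optimum is never worse than any lattice point.  Degenerate-case
rule: a von Mises with k -> 0 is itself uniform, so g is unidentified on
uniform data; when the mixture fails to beat the pure-guessing model by
more than a BIC penalty (ln n) the fit reports g = 1.  There is no
non-target ("swap") component because no distractor orientation exists in
this paradigm.

## Psychometric fits

Per-level clockwise counts at the ten signed offsets are fit by binomial
maximum likelihood to `P(CW|d) = lam + (1-2 lam) Phi((d - PSE)/sigma_p)`
with the lapse fixed at 0.01 (free in [0, 0.1] behind a flag).  The slope —
the sharpening index — is the derivative at the PSE,
`(1-2 lam)/(sigma_p sqrt(2 pi))`; the PSE is the shift index.  A full
Bayesian treatment of the psychometric function is out of scope: the
downstream analyses use only point estimates, and the tests rest on
synthetic-recovery properties rather than any particular prior.

## Group statistics

One-sample/paired t with Cohen's d = mean/sd of the (difference) scores;
one-way repeated-measures ANOVA with partial eta^2 =
SS_effect/(SS_effect + SS_error) and uncorrected df; Wilcoxon signed-rank
via the tie-corrected normal approximation (zero differences discarded,
variance reduced by sum(t^3 - t)/48) with effect size r = |z|/sqrt(n).
All p values are two-sided; no multiple-testing correction is applied.
Each statistic is cross-checked in the tests against an independent
implementation (pingouin, scipy) and, for the signed-rank test at small n,
against exact enumeration of all sign assignments.

## Problem sizes

The default cohorts are the study sizes: 24 participants for the profile
experiment (both tasks), 20 for adjustment, 18 for discrimination.
Recovery suites use 200 Monte-Carlo replicates (mixture at n = 768 = 16
blocks x 48 trials; psychometric at 16 trials/level); the null calibration
uses 1000 fast-mode cohorts; the staircase criterion check uses 200
replicate 40-trial staircases probed with 10,000 Bernoulli trials each.

## What the generator does and does not emulate

The generator reproduces the designs' probability structure, staircase
counts, trial counts, and the study's reported effect pattern (center-
surround DS profile with the dip at distance 20; precision gain at the
expected orientation; attraction of unexpected representations; slope gain
and expectward PSE shift).  It does not emulate sequential dependencies,
learning or fatigue across blocks, stimulus-level rendering, reaction
times, or decision biases beyond the fixed lapse — so passing tests
validate the estimators and pipeline under clean mixture/Weibull/Gaussian
assumptions, not the full richness of human data.
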