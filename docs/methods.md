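# Methods

`oculomet` turns 60 Hz tablet gaze recordings of four visual tasks into a
canonical profile of 20 oculomotor parameters per participant and relates
those profiles to multiple-sclerosis clinical scales (EDSS, SDMT, and the
BICAMS and MSFC composites).  Because no patient recordings ship with the
package, a synthetic cohort generator with fully known ("planted")
generative parameters stands in for the study data; every stage is
validated by recovering what was planted.

## Task battery

The simulated protocol mirrors a tablet-based testing session:

* **Fixation** — 7 s per location at five locations (center, ±10°
  horizontal, ±14° vertical).
* **Pro-saccade** — 24 trials over 8 locations × 2 eccentricity classes
  (short 5° horizontal / 6° vertical; large 10° / 12°), 3 repeats per
  location; pre-target fixation uniform 1.0–3.5 s, target shown 1.5 s.
* **Anti-saccade** — target flashed 100 ms at ±10°, 1200 ms blank, 400 ms
  arrow cue at the mirror location, 5 s answer screen.  The trial count is
  not fixed by the protocol description; the default is 16 (8 per side),
  which keeps the task under ~3 minutes while leaving workable
  denominators for the error and correction rates.
* **Smooth pursuit** — step–ramp trials: the target steps 1.5° opposite
  the motion direction, then ramps at 8.65 deg/s until reaching 10°
  eccentricity; one trial per cardinal direction.  (Protocol sources
  quote both 8 and 8.65 deg/s for this task; the velocity is an exposed
  parameter defaulting to 8.65.)

## Saccade model

Saccades are generated and fitted with the same parametric position
template: a truncated logistic ramp along the saccade axis,
parameterized by onset `t0`, amplitude `A` (deg) and peak velocity `Vp`
(deg/s).  The main sequence ties `Vp` to `A` through

    Vp = η · (1 − exp(−A / c)),

with ceiling `η` (bounded [50, 1200] deg/s, default 500) and amplitude
scale `c` (bounded [1, 20] deg, default 6).  A single waveform constrains
(η, c) only through `Vp`, so the fitter holds `c` at its default and
solves η (re-solving `c` only if η must be clipped); the identity above
holds exactly for every fitted event.  Using one family for both
generation and fitting makes planted parameters exactly identifiable:
noiseless templates are recovered to well under 1% in `A` and `Vp`.

Fitting works on *position*, not differentiated velocity.  At 60 Hz a
10°/405 deg/s saccade lasts ~46 ms — under three samples — so any local
derivative underestimates the true peak substantially (the best possible
one-interval estimate recovers ≲ 83%); the position template has no such
ceiling.

## Preprocessing and detection

* **Artifact handling**: sensor-invalid runs ≤ 75 ms (dropped frames) are
  linearly interpolated and flagged; longer runs (blinks) are masked with
  a 50 ms guard margin.  The usable-sample mask is derived purely from the
  recorded validity flags, so the operation is idempotent.
* **Velocity**: Savitzky–Golay differentiation (order 2, window 5) for
  analysis velocities (exact on the pursuit ramp); a moving-average
  difference ("boxcar", half-width 4 samples) for detection.  The boxcar
  slope is the matched estimator for a step in white noise, which is what
  a 1–2 sample saccade looks like at this rate.
* **Detection**: adaptive threshold = median + λ × (1.4826 · MAD) of
  speed over non-saccadic samples, iterated twice so detected events do
  not inflate their own threshold.  Supra-threshold runs ≥ 15 ms are
  candidate events; runs closer than 25 ms merge; onsets/offsets refine
  to the bracketing local speed minima; displacements < 0.5° are
  discarded (the hardware does not resolve microsaccades).  λ = 3 and the
  boxcar window were fixed by a simulation design study at the device
  noise level (0.33° RMS): the operating point delivers ≥ 0.97
  sensitivity for ≥ 1° saccades at ≤ 0.07 false alarms/s.  Classical
  λ ≈ 5–6 settings assume 250–1000 Hz data and are far too conservative
  at 60 Hz, where a 1° saccade yields only a ~4σ velocity excursion.
* **Onset estimates** used by latency metrics come from the fitted
  template `t0` (median error ~3 ms), not the detector bracket, which is
  several samples wide at this rate.

## The 20 parameters

* **Fixation (3)**: BCEA95 = 2π·k·σx·σy·√(1−ρ²) with k = −ln(0.05) ≈
  2.996 (bivariate-Gaussian form; a rank-based robust variant is
  available behind a flag); saccadic-intrusion rate (all detected
  saccades ≥ 0.5° during fixation per usable second — both members of a
  square-wave-jerk pair count); mean intrusion amplitude (pooled over
  events).  The first 0.5 s of each trial (target acquisition) is
  excluded; trials with < 1 s usable data are dropped.
* **Pro-saccade (8)**: latency (first saccade ≥ 1° in an 80–800 ms
  window), time-to-target (gaze within 2° of the target sustained
  ≥ 100 ms), peak velocity and amplitude gain (fitted amplitude /
  eccentricity) — each averaged separately over short and large
  eccentricity classes.  Vertical targets use vertical eccentricities as
  gain denominators.
* **Anti-saccade (5 + 1 optional)**: the first horizontal saccade ≥ 1°
  in the response window classifies the trial (toward the flash = error);
  an opposite saccade before the answer screen converts an error to
  corrected.  Derived: error rate, correction rate (of errors), correct-
  and incorrect-direction latencies, time-to-correct, and an optional
  21st column, time-to-target (offset of the final saccade landing in
  the correct hemifield).  Empty denominators produce structural missing
  values, never silent drops.
* **Pursuit (4)**: velocity gain = mean desaccaded along-track velocity /
  target velocity over the ramp (excluding the first 250 ms); an extra
  MAD-clip around the trial median removes residual sub-threshold
  catch-up samples before averaging.  Lag = mean gaze–target distance;
  proportion of time in pursuit = non-saccadic fraction of the ramp;
  catch-up count = co-directional saccades during the ramp, summed over
  the four trials.

## Clinical composites and statistics

BICAMS = mean z(SDMT, RAVLT, BVMT-R); modified MSFC = mean z(SDMT,
−T25FW, 1/9HPT), so "higher is better" holds componentwise.  z-scores
are cohort-internal with the sample-SD (n−1) convention (an external
norms hook exists).  Participants missing any component get a missing
composite.

Associations are Spearman correlations (average ranks; exact permutation
p below n = 10 without ties, t-approximation otherwise) over
pairwise-complete observations, with Benjamini–Hochberg control applied
within each outcome's family of 21 parameters (a global-family option
exists; the per-outcome scope is recorded in the output metadata).  The
EDSS contrast z-scores each parameter against the whole cohort, splits
at EDSS ≤ 4 vs ≥ 4.5, and uses two-sided Mann–Whitney U (exact when the
smaller group has < 20 tie-free observations, otherwise the
tie-corrected normal approximation).

## PLS models

PLS1 (NIPALS, internally standardized columns) estimates each outcome;
with as many components as full-rank predictors it equals OLS, which the
tests exploit as a closed-form oracle alongside a cross-check against
scikit-learn's `PLSRegression`.  The component count minimizes 5-fold CV
MSE with ties broken toward fewer components.  Note that with an
exactly collinear outcome the full-component (OLS) model *is* the CV
minimizer — a one-component fit carries finite-sample covariance with
every other predictor — so "one latent direction ⇒ one component" holds
only when the predictors themselves are rank-one.

Feature search: every candidate subset of oculomotor parameters is
augmented with age (never dropped), restricted to its own complete cases
(missingness is mostly structural), tuned and fitted, and scored by
in-sample R² (adjusted R² is reported and selectable).  Full exhaustive
search over 21 parameters (~2×10⁶ subsets × CV) is offered but the
default caps subset size at 8 or uses greedy forward selection; both
record a not-exhaustive flag in the model report.  Standardized
coefficients are βstd = b·sd(x)/sd(y); contribution weights are
|βstd| normalized to sum to one.  Reported R² is in-sample (CV-R² is
reported alongside).

## Synthetic cohort: what it emulates, what it does not

A latent severity u ~ U(0, 1) drives everything: clinical scores are
monotone functions of u plus truncated Gaussian noise anchored to a
published MS cohort's summary table (EDSS 1–7.5 after half-step
quantization, SDMT ≈ 50 ± 13, right-skewed T25FW/9HPT), and the planted
oculomotor truths shift with u in the clinically reported directions
(longer latencies, lower η, larger fixation scatter, more intrusions and
anti-saccade errors, lower pursuit gain).  Between-subject jitter is 15%
of each effect slope.  Traces add: an Ornstein–Uhlenbeck fixational
wander (τ = 0.3 s) with stationary covariance (σx, σy, ρ); square-wave-
jerk pairs (return saccade after 200 ms) at Poisson times; pursuit at
gain × target velocity from a 200 ms pursuit onset, with catch-up
saccades fired when the along-track error exceeds 1.8° (landing one
planted lag behind the target, so catch-up rate is emergent, not a
dial); Poisson blinks of 100–300 ms; white sensor noise of 0.33° RMS
(the emulated device's precision) and an optional constant accuracy
offset (the device figure is 0.47°; default off so planted positions
stay interpretable).

Because one latent variable drives all effects, *every* parameter
correlates with every outcome in a simulated cohort — the 21/21
significant cells in the example run are by construction, not a claim
about real data, where effects are weaker, noisier and not rank-one.
Passing tests demonstrate that the extraction and statistics machinery
is faithful (planted values come back out; error rates are controlled
under the null), not that the tablet device or the clinical effect sizes
are as modeled.  Other known gaps: no pupil data, no vergence (traces
are cyclopean), no head motion, white sensor noise without the temporal
structure of camera-based gaze estimation, and no microsaccades.

## Numerical choices and problem sizes

Detection and recovery benchmarks use 100 simulated trials and a
60-participant cohort; PLS validity uses 100 replicates of a planted
3-of-12-feature signal at n = 100 (search capped at size 4); null
calibration uses 200 replicates at n = 60 (greedy search, half the
replicates for the costlier model-selection arm).  These sizes give
Monte-Carlo standard errors comfortably below the asserted tolerances
(e.g. binomial SE < 1% at 800 planted saccades).  Degenerate inputs are
defined, not special-cased: all-equal gaze points give BCEA 0;
zero-error anti-saccade blocks give missing correction rates; an
all-masked velocity trace yields an empty event list.
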