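# Methods

## Scope and data model

The package analyses one recording session at a time.  A session bundle
holds a channels × bins matrix of multi-unit spike counts on a fixed 50 Hz
grid (bin *k* covers [k/50, (k+1)/50) seconds), a trial table with phase
onsets, an electrode-array map (array id, 10×10 grid position, mediolateral
coordinate in [0, 1] with 0 most lateral), and — for the velocity tasks — a
kinematics table sampled on the same grid (vx, vy, vz in workspace units/s,
grasp velocity vg in aperture units/s, phase label, click state).  Raw
voltage processing (filtering, threshold crossing detection) is out of
scope; the pipeline starts from spike events or binned counts.

## Preprocessing

Counts are converted to rates by causal convolution with a truncated
exponential kernel: k[j] = exp(−j·Δt/τ) for j = 0 … (window/Δt − 1),
normalised to unit sum, with Δt = 20 ms, window = 440 ms and τ = window/4
(so the kernel decays by ~e⁻⁴ across its support).  "Exponential smoothing
with a 440 ms window" admits several readings; this one keeps the filter
causal, conserves total spike count (up to edge truncation of at most one
kernel length), and exposes both τ and the truncation as parameters.
Rates are z-scored per channel over the whole session by default (an epoch
mask is accepted for per-task normalisation); channels whose rate variance
falls below 10⁻⁶ (spikes/s)² are flagged inactive and excluded downstream.
Whether normalisation should be per session, per block or per trial is an
open choice; whole-session is the simplest defensible default and the mask
makes sensitivity analyses cheap.

## Somatotopy mapping

For each movement type, z-scored rates are aligned to Movement onset,
averaged over that movement's trials on a grid spanning [−0.5 s, trial
end], and reduced by PCA (time bins as observations, channels as
variables, per-variable centering).  The time of peak |PC1 score| within
the Movement phase defines t_M; using the magnitude sidesteps the sign
ambiguity of principal components.  The 500 ms (25 bin) response window is
centred on t_M and shifted to fit inside the phase when t_M falls within
250 ms of an edge.  The time support of the PCA (whole trial vs Movement
phase only) is not uniquely determined by the procedure's description; the
[−0.5 s, trial end] support is one defensible reading and is localised in
a single function.

Tuning per channel × movement: raw spike counts in the response window
minus raw counts in the 500 ms immediately before Movement onset, one
signed difference per trial, tested against zero with a two-tailed
one-sample t-test.  Family-wise error is controlled by Bonferroni across
the four movements (per-test α = 0.05/4 = 0.0125).  Zero-variance
difference samples are degenerate: t = 0, p = 1, never significant.
Depth of modulation uses the smoothed rates instead of raw counts (the two
quantities deliberately mirror the count-based test and the rate-based
depth): per trial, the response-window rate series minus that trial's mean
baseline-window rate, keeping the excursion of largest magnitude with its
sign, averaged over trials.  Array-level proportions divide the channels
significant for a movement by the channels significant for at least one
movement on that array, so proportions may sum above one across movements.

## Movement classification

Features are per-trial total spike counts per active channel in the
response window of the trial's movement type.  The classifier is Naive
Bayes with uniform priors (the design is balanced by construction) and a
fixed posterior tie-break in canonical movement order (grasp, wrist,
elbow, shoulder).  The emission family is not pinned down by the
procedure; Gaussian per-feature emissions with a variance floor of
1e-9 + 1e-3 × (mean training-set feature variance) are the default, and a
Poisson-rate variant is available since the features are counts.
Evaluation is full leave-one-out cross-validation; held-out predictions
are pooled into confusion matrices per session and across sessions.

Two properties of this evaluation are worth knowing.  First, the response
window is selected from the full session before cross-validation (as in
the procedure the pipeline follows), so on information-free data the
selection couples a movement's features across trials and the pooled null
accuracy is over-dispersed relative to a pure binomial around 25%.
Second, leave-one-out on permuted labels over informative features is
biased below chance (the anti-learning effect: removing the held-out trial
shifts its class mean away from it); chance-level checks therefore use
populations with no movement information rather than label permutation.

## Velocity decoding (indirect OLE)

Encoding: each channel's z-scored rate is modelled as
f = b0 + bx·vx + by·vy + bz·vz + bg·vg, fit by ridge least squares with
the intercept unpenalised.  All channels share the velocity design, so the
solution is one linear solve for every channel.  The ridge penalty is
selected per cross-validation fold by 5-fold inner CV over a log grid
(10⁻³ … 10³) on training bins; a fixed-λ mode exists for deterministic
tests.  Decoding inverts the stacked encoding:
v̂ = (BᵀB + γI)⁻¹ Bᵀ (f − b0), with γ = 10⁻⁶·trace(BᵀB)/d by default — a
small stabiliser, not a tuned parameter.

Evaluation is leave-one-trial-out.  Translation models are fit on reach
and carry phase bins, the grasp model separately on grasp and release
bins; "movement period" bins are those whose presented speed exceeds 1% of
the per-trial peak.  Held-out predictions are concatenated and scored as
squared Pearson correlation per dimension; translation r² averages (X, Y,
Z) for the virtual-arm task and (X, Y) for the cursor task, grasp r² is
scored on vg alone.  Dimensions with zero actual variance in the mask are
undefined and excluded.  The three channel conditions (both arrays, medial
only, lateral only) rerun the identical procedure on the corresponding
channel subsets.

## Click-state HMM

Clicked vs unclicked time points are decoded with a two-state hidden
Markov model.  Training is supervised: the emission projection is the
Fisher linear discriminant between the labelled states (computed with
shrinkage, `eigen` solver — smoothed rates are temporally correlated, so
the effective sample count is far below the bin count and an unshrunk
within-class covariance overfits); emissions are state-conditional
Gaussians on that 1-D projection; transitions are label bigram frequencies
with add-one smoothing; the start distribution is the label frequency.
Decoding is offline Viterbi (causal filtering is a non-goal).  Evaluation
is leave-one-epoch-out, where an epoch runs from one click onset to the
next; accuracy is the fraction of correctly labelled time points pooled
over held-out epochs.

## Group statistics

Per task and metric, the sessions × conditions table is tested with a
Friedman test (chi-square reference; a table whose rows are all constant
is degenerate: statistic 0, p 1).  Pairwise Wilcoxon signed-rank tests for
the three condition pairs are computed only when the Friedman test is
significant at α = 0.05, at the Bonferroni-corrected threshold 0.05/3.
Zero differences are dropped; the exact null distribution is used for
n ≤ 25 remaining pairs and the normal approximation with continuity
correction above.  The zero-handling and exact-vs-approximate policy are
recorded in the run manifest.

## Synthetic population and sessions

The generator is the test bed for every analysis above, with ground truth
exposed for parameter recovery.  What it emulates, and what it does not:

* **Arrays** — two 10×10 grids ("lateral", "medial") of 96 channels each by
  default; each channel's mediolateral coordinate spans [0, 0.4] (lateral)
  or [0.6, 1.0] (medial) along its grid columns.
* **Baseline firing** — per-channel baselines drawn N(15, 5²) spikes/s,
  floored at 1 (multi-unit threshold-crossing rates, not single units).
* **Tuning gradient** — a configurable fraction (default 0.5, within the
  reported range of movement-modulated channel proportions) of channels is
  untuned; tuned channels get per-movement signed depths whose expected
  magnitude is depth_base + slope·depth_span·x with x = pos for proximal
  movements (elbow, shoulder) and 1 − pos for distal ones (grasp, wrist),
  defaults 4 + 12·x spikes/s, lognormal spread (CV 0.3), random sign.
* **Somatotopy task** — Baseline 3 s / Movement 3 s / Rest 2 s (the task
  description's text values; the figure caption's 2/3/3 variant is reachable
  through `phase_durations_s` since the two disagree), 20 blocks of the 4
  movements in block-randomised order (80 trials).  Within the Movement
  phase the rate is baseline + depth·w(t) with w a raised-cosine bump
  (0 at the phase edges, 1 at its centre) — the time course is not
  specified by the source procedure; the bump gives a well-defined t_M for
  recovery tests.  Counts are Poisson per bin, or cumulative-rounded
  deterministically when `poisson=False`.
* **Encoding** — z-scale drive f = b0 + B·v plus N(0, noise_scale²) per
  bin, converted to rates as max(0, baseline + rate_sd·f) with
  rate_sd = 10 spikes/s per z-unit (simulation needs this direction; the
  analysis never does).  Translation coefficients are drawn with SD
  proportional to a proximal weight 0.35 + 0.65·pos, the grasp coefficient
  to the mirrored distal weight, and a second distal-weighted 2-D set
  drives wrist-imagery cursor sessions.  The weight floor 0.35, coefficient
  SDs (0.35 translation, 0.15 grasp) and noise_scale = 1 were chosen once
  so that per-channel encoding r² sits in the few-percent range typical of
  multi-unit channels and population decoding lands in the r² ≈ 0.4–0.8
  regime with the medial/lateral contrast clearly resolved at the default
  session sizes.
* **Virtual-arm task** — 30 trials (within the typical 18–36 calibration
  range) of idle / minimum-jerk 3-D reach / grasp close / carry / release
  segments; minimum-jerk speed peaks at 1.875·D/T.
* **Cursor task** — center-out to 8 equally spaced targets, 40 trials by
  default; 12 or 13 click-and-drag epochs per session, a click being
  pressed at target arrival on a click trial and released at the next
  target arrival.  Click information is carried entirely by the grasp
  coefficient: a transient grasp velocity at press/release plus a
  sustained bg·click_hold_scale drive while held (default 2, set so that
  informative sessions reach the ~0.85–0.95 accuracy range reported for
  hand-area arrays).  Balanced clicked/unclicked durations are obtained
  with 26 trials / 13 epochs (alternating click trials).
* **Determinism** — one RNG stream per session, seeded; identical
  (population, config, seed) give bit-identical bundles.

Not emulated: raw voltage, spike waveforms, LFP, inter-channel noise
correlations, electrode degradation, behavioural response-time variability,
imagery non-compliance.  Passing tests therefore demonstrate that the
analysis code is correct and well-calibrated under Poisson-like firing with
linear velocity encoding — not that the biological effects would reach the
same magnitudes in real recordings.

## Numerical choices and degenerate inputs

Zero-variance channels are excluded before PCA, classification and
decoding.  Zero-variance t-test samples give p = 1.  A rank-deficient
velocity design with λ = 0 raises rather than silently pseudo-inverting.
Decoding requires ≥ 4 usable channels; r² is undefined (NaN, excluded)
when either series has no variance.  Posterior ties in the classifier go
to the first label in canonical order.  Friedman tables with missing cells
raise; all-constant rows short-circuit to the degenerate result.  Problem
sizes in the test and acceptance runs (5 sessions, 96-channel arrays,
default trial counts) match the study conditions above; the chance-level
reference computations use the same sizes with the relevant ground-truth
terms set to zero.
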