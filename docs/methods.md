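# Methods

## Scope and conventions

`gaitvid` computes spatiotemporal gait variables from 2D pose-keypoint time
series recorded by a fixed hallway camera at 30 fps, and relates
participant-level baselines to mobility scores and prospective fall counts.
All coordinates are image coordinates: `x` is the column, `y` the row, `y`
increasing downward. Every "vertical" computation negates `y` internally so
that *up is positive*; all pixel distances are divided by the mediolateral
hip span (pixel distance between the left and right hip keypoints), making
every reported variable dimensionless and invariant to global scaling and
translation of the image coordinates (an invariance the test suite enforces
at 1e-6 relative tolerance).

The keypoint schema holds 13 labels. Six are structurally required
(`left_hip`, `right_hip`, `left_ankle`, `right_ankle`, `head_top`, `neck`);
the remaining seven default to an MPII-style limb set (shoulders, elbows,
knees, pelvis) and are configurable, since only the required six enter the
gait math and the head pair enters PCKh normalization.

## Preprocessing

Keypoints with detector confidence strictly below 0.4 are discarded
(`= 0.4` is kept) and re-filled by linear interpolation between the nearest
accepted samples, with constant extrapolation at bout edges. A required
keypoint with fewer than two accepted samples rejects the bout with a
diagnostic. Imputation runs *before* filtering: filtering through dropout
gaps would smear gross detector errors into neighbouring frames. The
low-pass filter is a 2nd-order Butterworth at 4 Hz, applied forward-backward
(`filtfilt`). Zero-phase filtering is the biomechanics standard because it
preserves event timing; the cost is an effective doubling of the order,
which is documented rather than compensated. Normalization is per-frame by
default (a bout-median policy is available for very low spans); frames whose
hip span falls below a 1 px floor are dropped from whatever statistic is
being computed.

## Foot-strike detection

The vertical velocity of each ankle keypoint is the central difference of
its filtered vertical position. During swing the ankle rises, then descends
into landing; the landing appears as a peak of *downward* velocity that
decays toward zero as the foot meets the ground. Detection, per ankle:

1. candidate landing peaks are local maxima of downward speed of at least
   25% of the signal's global downward maximum, separated by the refractory
   interval (0.25 s default);
2. each peak defines a step cycle whose maximum is the speed at that peak;
3. the strike is the first later sample where downward speed decays through
   35% of the cycle maximum;
4. strikes closer than the refractory interval to the previous one are
   dropped.

The 35% threshold is relative, so detection is invariant to pixel scaling
and to constant position offsets. Whether the published 35% rule applies to
signed velocity or speed, and how cycles are segmented, is not fully
recoverable from its source; the choice above (crossing on the decaying limb
*after* the downward peak) places strikes at ground contact rather than at
peak descent and is verified against an independent per-sample brute-force
evaluation of the same definition. The refractory interval and peak-height
floor are not part of the published rule; they guard against double
crossings under noise and are configurable. On synthetic bouts strikes land
within 1–2 frames of true contact; the residual bias is systematic (the
filter delays the decay of short, fast swings slightly more than long ones)
and cancels almost entirely in step-time differences.

Stance assignment: the stance foot at any time is the foot of the most
recent strike at or before it (frames before the first strike take the
first strike's foot, but feature averages skip them). This is the simplest
deterministic rule consistent with single support; double-support intervals
are not modelled.

## The seven variables

* **cadence** — merged strikes of both feet divided by bout duration in
  minutes. Steps, not strides.
* **SI of step time** — each inter-strike duration is attributed to the
  foot that struck ("time spent on each foot"); SI = |T_L − T_R| /
  ((T_L + T_R)/2) ∈ [0, 2]. The total is attributed step time, not bout
  wall-clock. An alternative reading (per-foot stance time) is possible;
  attributed step time is the default and the generator defines its truth
  the same way.
* **CV of step time** — sample (n−1) standard deviation over mean of the
  inter-strike durations. The n−1 convention is used for every CV.
* **average step width** — per-frame horizontal (image-x) ankle separation
  in hip-span units, averaged over valid frames.
* **CV of step width** — widths sampled once per step at strike frames, so
  that this CV operates on a per-step quantity exactly like the step-time
  CV; a per-frame alternative sits behind a config switch.
* **average / minimum eMOS** — eCOM is the hip midpoint; its lateral
  velocity is the central difference of the filtered eCOM (the same chain as
  the ankles), normalized *after* differencing so a constant image offset
  cannot leak into the extrapolation. eXCOM = eCOM_norm + v_norm/√(g/ℓ) with
  g = 9.81 and ℓ the normalized leg length (hip→ankle distance at each
  foot's strike frames, averaged per foot, then between feet; a foot with no
  strikes borrows the other's mean). g enters against a normalized,
  unit-free leg length — a deliberately relative construction, configurable.
  eMOS(t) is the signed normalized lateral distance from the eXCOM to the
  stance ankle, positive when the ankle lies lateral (outward of the eCOM
  midline) of the eXCOM. The average is over frames from the first strike
  on; the minimum variant averages each inter-strike step's minimum (the
  trailing partial step after the last strike is excluded). Both use signed
  values.

Bouts with fewer than 3 detected strikes are flagged `too_few_steps` and
rejected; manual exclusion flags (handrail, turned-around, occluded) always
dominate. Undefined features are recorded as absent, never zero. Baselines
average retained bouts recorded within 14 days of enrollment.

## Keypoint verification (PCKh)

A predicted keypoint is correct when its Euclidean distance to the manual
annotation is ≤ α × the annotated head-segment length (head_top–neck) of
that image, α = 0.5 by default; ties count as correct. The confidence sweep
recomputes PCKh after discarding predictions below each cutoff
(0.2/0.4/0.6/0.8 by default) and reports the discarded fraction — the
trade-off used to justify the 0.4 imputation threshold.

## Cohort models

OLS with intercept for POMA sub-scores (two-sided slope p-values; a
constant outcome is reported as R² = 0 rather than undefined). Fall counts
use a log-link Poisson GLM with log observation-days as offset, so
coefficients describe rates; tests are two-sided Wald. Pseudo-R² is
deviance-based, 1 − D_res/D_null, with the adjustment
1 − (D_res/(n−k−1)) / (D_null/(n−1)). No standard adjustment can make the
adjusted value exceed the unadjusted one, so reported adjusted values are
always ≤ R²; this is stated prominently because deviance adjustments vary
across software. Multivariate selection: keep univariately significant
features (p < 0.05); among any pair with |Pearson r| > 0.8 keep the one
with higher univariate pseudo-R² (greedy, strongest first). Records with
missing values are excluded listwise per model; non-convergence is reported
in the result, never silently dropped.

## Synthetic data

The bout generator emulates the capture geometry — a walker approaching a
ceiling-mounted camera — as isotropic scale growth (default 1.5× over the
bout) applied to a unit-skeleton: hips one hip-span apart with sinusoidal
lateral sway at stride frequency; the stance ankle planted; the swing ankle
following a half-sine-squared vertical arc whose landing produces a clean
decaying downward-velocity limb for the 35% rule. Swing time is a fixed
share (0.7) of the *average* step, so programmed step-time asymmetry loads
onto stance time, as in real asymmetric gait; an earlier variant that
scaled swing with each foot's own step biased SI recovery through
asymmetric filter distortion and was corrected. Gaussian pixel noise
(default 1 px), confidence dropouts (low confidence + large displacement)
and an optional half-scale "assistant" track emulate detector failure modes.
Defaults (10 s bouts, 100 steps/min, width 0.5, 100 px starting hip span)
are study-like magnitudes. What the generator does *not* model: pinhole
perspective (only isotropic scaling), double support, soft-tissue or
clothing artefacts, track identity switches, and camera motion — so passing
tests demonstrate correctness of the estimators under the stated kinematics,
not detector robustness on real video.

Ground truth records contact times, single-support intervals, per-step
widths, the clean eCOM path, and realized features. The "true" cadence/SI/CV
are computed from the *emitted* contact schedule (realized values), not the
programmed rates, so recovery tolerances measure detection fidelity rather
than schedule truncation at bout edges.

The cohort generator draws 31 participants' baseline features from a
multivariate normal with an 0.9 correlation between the two eMOS variables
(they are statistics of the same signal) and independent remaining features;
exposures are normal (44 ± 19 days, clipped to 14–90); falls are Poisson
with rate exp(β₀ + β·(x − μ)) per day, β₀ anchored at ~1.4 falls per 44
days; POMA scores are linear in designated features plus noise, rounded and
clipped to their scale ranges (0–12 gait, 0–16 balance). Default effect
sizes are 0.9 per feature-sd for cadence and average eMOS: a power
calculation at these count magnitudes shows weaker effects (≈0.45/sd, Wald
z ≈ 2.9) cannot yield the near-certain univariate significance that the
selection-rule scenario requires, while 0.9/sd gives z ≈ 4 and ~98% joint
retention. The calibration checks (type-I error, coefficient recovery) set
the coefficients explicitly (all zero, or cadence = 0.03) and do not depend
on these defaults.

## Numerical and scale choices

Problem sizes in the tests and acceptance script — 100-bout recovery
sweeps, 2000 null simulations, 500 recovery replicates, 200 selection
replicates, 100-bout pipeline manifests — were chosen so the full battery
runs in well under a minute on one CPU while keeping Monte-Carlo standard
errors a few times smaller than the tolerances they check. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`.
Degenerate inputs are handled by explicit policy: empty strike lists report
no events; a zero null deviance makes pseudo-R² undefined (reported, not
raised); hip spans below the pixel floor drop frames; missing fps is a
configuration error.

## Known limitations

2D pixel geometry cannot produce absolute step length or walking speed.
eMOS here is a relative, unitless analogue of the margin-of-stability
construct, not comparable to force-plate values. The foot-strike rule's
published source is under-specified; a different reading (e.g. thresholding
the signed rise before landing) would shift strikes by a constant fraction
of swing time, leaving cadence and CV nearly unchanged but shifting SI
slightly. Track selection assumes the participant is the largest figure;
identity switches mid-bout are not detected. The Poisson models assume
constant per-day fall rates over each participant's observation window.
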