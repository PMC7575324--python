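# Methods

This note documents the models, parameter choices, numerical decisions,
and limitations behind `locoblink`. All defaults named here are the
package defaults; everything quantitative stated below is computed by the
test suite or by `scripts/acceptance.py`.

## Eyelid video analysis

The eye appears as a bright elliptical region in a pre-cropped grayscale
frame (the acquisition geometry emulated by the synthetic frames is a
172 × 160 px window sampled at 900 Hz). Per frame, the image is binarized
(Otsu's threshold by default, with a manual override), the largest
connected foreground component is kept, and the **eyelid distance** is
the full minor-axis length of that component's second-moments ellipse.
The second-moments fit was chosen because it is deterministic and closed
form; for a clean rendered ellipse it recovers the minor axis to well
under a pixel, and the minor-axis length is invariant to in-plane
rotation. A frame with no foreground is reported as distance 0 with a
closed-eye flag rather than an error, since full blinks legitimately
produce such frames.

**Session normalization.** Raw distances are mapped to closure
c = (d_open − d)/(d_open − d_closed), clipped to [0, 1], with 1 = full
blink. The anchors are session-wide robust statistics rather than
extremes: d_closed is the 1st percentile of all frame distances (paired
trials guarantee full blinks, so the low tail is the blink distance) and
d_open is the 97.5th percentile of pre-CS baseline distances. Percentiles
guard against tracking glitches; both percentiles and explicit anchor
overrides are exposed because the choice between extremes and robust
statistics is a genuine free parameter of this stage.

## Conditioned-response metrics

A trial is a **CR** when normalized closure reaches at least 0.1 within
[CS onset + 100 ms, US onset); the lower bound is inclusive, the US-onset
bound exclusive, and "reaches" means the threshold value itself counts.
Window membership is decided with a half-sample tolerance so that a
sample nominally on a boundary is classified identically at any sampling
rate. On CS-only trials the amplitude window extends 50 ms past the
would-be US onset (through the co-terminating stimulus), and the peak
time relative to CS onset is reported — well-timed CRs peak near the ISI.

%CR of a session counts both paired and CS-only trials in the
denominator; all CS-bearing trials are classifiable, and the choice is
configurable since conventions differ. The learning-onset session is the
first whose mean CR amplitude strictly exceeds 0.1.

**Locomotor state.** Per trial: distance (mean speed × window duration),
mean speed, fraction of samples above a 0.01 m/s walking threshold, and a
stationary flag for mean speed < 0.05 m/s. "Ambulatory" is the complement
of stationary. The 150 m/session cut splits animals into top/bottom
runners. Speed-binned amplitude curves are computed per animal and then
averaged across animals, with empty bins reported as missing (absence is
not zero); per-animal trial-fraction histograms sum to 100%.

**Statistics.** Trial-level amplitude–speed coupling uses a linear mixed
model with random slopes and intercepts per mouse (statsmodels MixedLM,
REML). The fixed slope is tested by an F test with **Satterthwaite**
denominator degrees of freedom. No installed Python package exposes
Satterthwaite df for mixed models, so the standard approximation is
implemented in `stats.py`: with f(θ) = L′Cov(β̂)L over the variance
parameters θ (random-effect covariance entries and the residual
variance), ddf = 2f²/(g′Ag), where g is the finite-difference gradient of
f and A the inverse negative finite-difference Hessian of the restricted
log-likelihood. The likelihood is evaluated through the Woodbury identity
on per-group cross-products, so each evaluation is O(q³) per group. On a
10-mouse × 200-trial table the implementation agrees with `lmerTest` to
four significant figures (slope, se, ddf, p), and its frozen values are a
test oracle. Calibration, measured by the suite: 95% CI coverage 94/100
seeded cohorts; type-I error 0.050 at 500 null replicates. Degenerate
likelihood surfaces (zero variance components) fall back to a
between-group residual df.

Animal-level onset-vs-activity fits use bisquare-weighted IRLS
(c = 4.685, MAD scale, tolerance 1e-8, max 50 iterations) — an
outlier-resistant line whose slope matches statsmodels RLM on the same
data; the dual route is kept as a test. Single-trial learning effects
partition trials by previous-trial US presence, excluding the first trial
of each session.

## Gait parameterization

Tracks are (x, y, z) paw positions (mm) for FR/FL/HR/HL plus a
body-center x, with x the forward axis. **Stride segmentation** runs peak
detection on the paw's forward excursion relative to the body: stance
onset (touch-down) at local maxima, swing onset (lift-off) at local
minima, with prominence 20% of the excursion range and minimum separation
50% of the stride period estimated from the dominant Fourier component.
Detected events are forced to alternate starting from the first
touch-down; a constant track yields an empty stride set. The final
incomplete stride is dropped from parameter tables with its count
recorded.

Parameters follow the standard definitions: stride duration between
consecutive stance onsets, cadence its inverse, duty factor
stance/stride, stride length the touch-down-to-touch-down forward
displacement, swing velocity the swing displacement over swing duration.
On a treadmill, per-paw displacement over time is computed in the ground
(belt-compensated) frame — the config flag defaults to ground frame —
while instantaneous between-paw distances (step length, base of support)
are frame-independent and use raw positions. Stance phase is
(t_on − t_on,ref)/T wrapped to [0, 1) with FR as reference, the only
dimensionally sensible reading of the formula. Support categories use a
1 mm contact-height threshold and partition every frame into 3-paw,
2-paw-diagonal, 2-paw-other, and a remainder bucket, as fractions of
stride duration. Swing trajectories are resampled to 100 equidistant
points by linear interpolation, averaged within 0.05 m/s speed bins, and
smoothed with a first-order Savitzky–Golay filter with a 3-point window
(identical, on interior points, to a 3-point moving average — asserted
exactly in the suite). Variability is the coefficient of variation
sd/mean (sample sd).

On noise-free generator gaits every parameter matches its closed-form
value to within one frame period / 1 mm of quantization error.

**Discriminant.** Gait-parameter tables (one row per animal at a speed,
~45 z-scored features) are embedded by covariance eigendecomposition
(PCA, descending eigenvalues; the eigenvalue sum equals the retained
feature count after z-scoring), the leading 10 PCs feed an LDA, and
per-feature contributions to the LD axes are the product of the PCA and
LDA mappings. This is packaged as a scikit-learn transformer
(`GaitDiscriminant`) so it composes with sklearn pipelines; constant
features are dropped with a warning, and n_pcs must stay below the
observation count.

## Split-belt adaptation

Protocols are ordered baseline → split → washout trial lists (session
breaks allowed). Two built-ins mirror the original designs: a
single-session protocol (2 tied + 8 split + 8 tied; split 0.175/0.375
m/s, ratio ≈ 2.14) and a five-session protocol (3 tied + 7 split / 10 /
10 / 3 split + 7 tied / 10 tied; tied 0.2, split 0.125/0.275 m/s). The
single-session tied speed is not pinned down by the source design; 0.275
m/s (the mean of the split speeds, and a tied speed used in related
treadmill recordings) is the default and is configurable. Asymmetries
are fast − slow throughout; relabeling sides flips every sign but leaves
percent-of-initial-error unchanged.

Phase metrics: initial error = first split trial; change over split =
last − first split trial (strictly the first/last trials, not averages);
aftereffect = first washout trial − baseline mean. The
baseline-subtracted aftereffect is the default, with the raw-first-trial
variant behind a flag, because the two conventions coexist in the
literature. Percent adaptation normalizes |change| and |aftereffect| by
the group's mean |initial error|; taking magnitudes implements the usual
sign-inversion convention for display.

**Compliance.** Stance speed per side (mean |ẋ| of the front paw during
stance, treadmill frame) must match that side's belt speed within ±20%
on at least 80% of split trials — the criterion is configurable since no
numeric rule is standard.

**Group comparisons** use a mixed model over per-animal phase metrics
(one observation per animal per phase, animal as random intercept,
genotype × phase cell means), genotype contrasts within phase with
Satterthwaite t tests, and Tukey adjustment via the studentized-range
distribution over the six cell means. The statsmodels default optimizer
is used here; L-BFGS reports convergence on this design while stopping
short of the REML optimum.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions and are first-class, tested
code.

**Eyeblink cohorts.** Defaults mirror the acquisition design: 20 sessions
× (100 paired + 10 CS-only) trials, ITI uniform on 5–20 s, ISI 300 ms
with co-terminating 50 ms US (CS duration 350 ms), eyelid traces at
900 Hz, and two groups with activity means 0.12 (control) and 0.04 m/s
(hypoactive), per-animal and per-trial SD 0.03 m/s. Acquisition follows a
latent learning state L ∈ [0, 1] advanced after each paired trial by a
saturating logistic step, L ← L + g(1 + w·v)L(1 − L), with gain
g = 0.003, speed weight w = 20 (m/s)⁻¹, L₀ = 0.01 — a minimal model
producing activity-dependent learning onset (active group onset ≈ session
4, hypoactive ≈ session 8, earlier for the active group in 100/100
simulated cohorts). Trial amplitude is L·(0.3 + 2.0·v) plus N(0, 0.05)
noise, clipped to [0, 1]; traces carry a Gaussian CR ramp peaking at the
(would-be) US time, gated to start after the CS, and a UR reaching full
blink on paired trials, which anchors session normalization. The
dynamics are a stand-in, not a claim about biology: real acquisition,
trial-history effects, and eyelid kinematics are far richer, so passing
recovery tests demonstrates correctness of the *analysis*, not fidelity
of the learning model.

**Eye frames.** A bright ellipse on a darker background whose minor axis
scales linearly with openness (full-open minor axis 30 px by default);
no photorealism, pupil, or illumination structure.

**Gait.** Piecewise-linear periodic paw trajectories: stance moving
backward at belt speed (treadmill frame) or stationary (overground), a
sinusoidal swing-height bump (10 mm), duty factor 0.6, trot phases
(homologs at 0.5), body width 20 mm, 400 Hz, with a global phase offset
of 0.25 cycles so touch-downs avoid the record boundaries. Real paw
trajectories are not piecewise linear and real gaits drift in phase; the
generator's purpose is exact closed-form ground truth.

**Split-belt.** Baseline at 0; split jumps to the initial error and
decays exponentially (fraction r of the remaining error removed per
trial); washout starts at −retention × adapted amount and decays at the
same rate; i.i.d. Gaussian trial noise. Defaults: initial error −0.30,
r = 0.3, retention 0.8, noise 0.05. Single-rate exponential dynamics
omit the fast/slow two-process structure of real adaptation.

All generators are reproducible bit-for-bit from their seed
(`numpy.random.default_rng`).

## Problem sizes used by the checks

The acceptance script and suite run at sizes chosen to make the
statistical properties sharp while staying desk-scale: mixed-model
calibration at 10 mice × 200 trials (100 coverage cohorts, 500 null
replicates), onset-coupling at 6 mice/group × 20 sessions (60–100
cohorts), split-belt recovery over 100 seeds, gait round trips on 3 s of
400 Hz tracks. Group-level animal statistics from the original
experiments (specific t and F values on real cohorts) require the animal
data and are out of scope.

## Known limitations

- The Satterthwaite Hessian is finite-difference; at boundary estimates
  (zero variance components) it degenerates and the code falls back to a
  conservative residual df.
- Stride segmentation assumes a single dominant periodicity; gaits with
  strong within-trial speed changes should be segmented in shorter
  windows.
- `stance_speed_compliance` uses front paws only; hind-paw compliance is
  rarely the binding constraint but is not checked.
- The CLI covers the common single-input paths; multi-animal batch
  orchestration is left to scripts over the library API.
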