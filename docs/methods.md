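# Methods

## Problem and pipeline

`sitsway` analyses postural control measured in a *seated* position on a
four-load-cell balance board. Seated posturography isolates the
trunk-stabilising musculature from the lower limbs, which makes it a
candidate screening instrument for neuromuscular deficits associated with
chronic low back pain. The pipeline runs:

1. **Raw force channels → CoP.** Each trial is four corner forces
   (TL, TR, BL, BR in newtons) sampled at `sampling_rate_hz` (default
   1 kHz) for `trial_duration_s` (default 60 s). Channels are low-pass
   filtered, then combined into the planar centre of pressure
   `x = w·((TR+BR)−(TL+BL))/ΣF`, `y = l·((TL+TR)−(BL+BR))/ΣF`
   with `w`, `l` the board half-width/half-length (defaults: nominal
   Wii-board geometry, 25.5 × 15.8 cm).
2. **Features.** CoP path length (cm); PSD band powers over eight windows
   between the lowest resolvable frequency and 10 Hz; mean of the per-cycle
   maximum acceleration (cm/s²); ellipticity of the sway cloud.
3. **Staged QC.** Protocol flags → implausible-value rule (> 10⁶) →
   0.9·IQR fences per feature column.
4. **Statistics.** Per-feature Welch t-tests with group means and their
   difference; factorial ANOVA (anthropometry × pain) with η², ω² and
   post-hoc power; stratified mean (SD) summaries.
5. **Classification benchmark.** SVM, CART tree, random forest and a small
   neural network on repeated shared 70/30 splits, min–max normalised,
   reported as mean ± SD percent accuracy.

## Filtering

The low-pass is a third-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`), so the passband is phase-free and path-length
estimates are not distorted by group delay. The quoted −3 dB point refers
to the single-pass design magnitude; the zero-phase application squares the
magnitude response.

A single cohort-wide cutoff avoids re-shaping the anthropometry–signal
relationship per subject. With `filter_cutoff_hz: auto` the cutoff comes
from residual analysis: for each candidate cutoff the RMS residual between
the raw and filtered CoP is computed; in the noise-dominated region this
declines linearly with cutoff, so a line fitted to the upper half of the
candidate grid and extrapolated to 0 Hz estimates the noise floor, and the
smallest cutoff whose residual reaches that floor is selected; the cohort
cutoff is the median over recordings. Degenerate inputs (constant signals,
pure broadband noise with no knee) fall back to `filter_cutoff_max_hz` with
a warning. On default synthetic cohorts the selection lands at ~7 Hz. A
fixed numeric cutoff in the config overrides all of this.

## PSD and band powers

The default estimator is the mean-detrended, rectangular-window
periodogram, chosen because it conserves variance exactly; Welch
(`psd_method: welch`, segment length `welch_nperseg_s`) is available when
estimator variance matters more than exactness. Band powers integrate the
*resultant* density (sum of the ML and AP one-sided densities, making band
areas invariant to axis rotation) at bin resolution: each frequency bin
whose centre lies in the half-open window `[low, high)` contributes its
full `density × Δf`. This makes adjacent bands exactly additive and the
full-support sum exactly equal to the time-domain variance for the
periodogram; a trapezoid between bin centres was rejected because
half-weighting the first bin alone can lose >2% of the variance when slow
sway dominates. Densities are cm²/Hz, so areas are cm².

A nominal lower band edge of 0.001 Hz is far below the 1/60 Hz resolution
of a 60 s trial; such edges are clipped to the first positive bin with a
warning and mean "from the lowest resolvable frequency".

## Acceleration per movement cycle

Velocity and acceleration come from second-order central differences
(`numpy.gradient`) of the filtered track. A *movement cycle* is the span
between consecutive upward zero crossings of the anteroposterior velocity;
the feature is the mean over cycles of each cycle's maximum resultant
acceleration magnitude. The cycle definition is a package decision (any
oscillation delimiter would do); it matters because large slow sway
suppresses zero crossings, lengthening cycles and raising per-cycle maxima
— which is exactly how a short, slow, elliptical pain-type track can carry
*higher* peak accelerations than a longer healthy track.

## Ellipticity

The ratio √(λ₁/λ₂) of the principal-axis variances of the centred sway
cloud: 1 for circular patterns, ≈2 for strongly elongated ones. Collinear
clouds are capped at 10⁶ (or raise, when the cap is disabled).

## Quality control

* Implausible rule: any feature value strictly greater than 10⁶ drops the
  trial ("greater than" read strictly, so exactly 10⁶ survives).
* IQR fence: with type-7 (linear-interpolation) quartiles Q1, Q3 and
  IQR = Q3 − Q1, values outside [Q1 − k·IQR, Q3 + k·IQR] (k = 0.9) are
  excluded; a trial is dropped when any analysis feature falls outside its
  column's fence, computed on the pooled sample. The quantile convention is
  fixed because quartile definitions move borderline exclusions.
* Protocol failures (could not sit still for the full trial) are a boolean
  on the subject record, not detected from the signal.

On default synthetic cohorts the three stages retain ~75% of subjects,
with the exclusions concentrated in the heavy upper tail of the pain
group's band-power distribution.

## Group statistics

The two-group comparison reports means per group and the difference as
(no-pain − pain); Welch's t-test is the default because group sizes and
variances are typically unequal, with Student's pooled test selectable.
ANOVA uses OLS with Type II sums of squares (order-invariant on unbalanced
data; switchable). Effect sizes per term: η² = SS_term/SS_total and
ω² = (SS_term − df·MS_err)/(SS_total + MS_err), the latter slightly
negative for null effects by construction. "Power" is post-hoc power at
α = 0.05 from the noncentral F distribution with λ = F·df_term. Age is
excluded from the default model terms: cohorts of this kind usually cannot
age-match the pain group, and including age invites a pseudo-correlation.

## Classifier benchmark

Each of `n_repeats` (default 10) runs draws one random 70/30 split
(unstratified by default; a class missing from either side triggers a
resample with a warning) that is shared verbatim by all four models.
Min–max scaling is fitted on the training rows only; evaluation values
outside the training range are deliberately not clipped. Model defaults
mirror the common R implementations: RBF-kernel SVM with C = 1, CART tree,
500-tree random forest with √p features per split, and a single-hidden-layer
network (3 logistic units, L-BFGS training). The default feature set is
track length plus the 0.001–10 Hz and 0.001–4 Hz band powers — the bands
with the strongest group effect. Accuracy is plain percent-correct.

## Synthetic cohort generator

No public recordings of this kind exist, so the generator is a first-class
module. Each axis of a subject's CoP is a sum of narrowband stochastic
oscillators — constant-amplitude sinusoids whose phase diffuses with
increment variance 2π·bw·dt per sample, giving a Lorentzian line of full
width ≈ bw and expected power exactly a²/2 — plus a slow random-walk drift
(scaled to a fixed RMS) and white measurement noise. The AP axis is an
independent realisation with amplitudes multiplied by the ellipticity. The
component centre frequencies follow the effective pendulum lengths of
seated sway: thoracic spine ≈ 0.7–0.9 Hz, sacroiliac region ≈ 1 Hz, hip
axis ≈ 1.5–3 Hz, plus slower visuo-vestibular sway and faster muscular
corrections.

Group defaults (amplitudes in cm, per ML axis):

| group   | components (f₀ Hz, a cm)                                   | ellipticity | drift | noise |
|---------|------------------------------------------------------------|-------------|-------|-------|
| healthy | (0.3, 0.042) (0.8, 0.055) (1.0, 0.068) (1.8, 0.096) (2.4, 0.059) | 1.1   | 0.03  | 0.01  |
| pain    | (0.25, 0.233) (0.7, 0.055) (1.0, 0.030) (2.8, 0.029) (4.0, 0.014) | 2.0   | 0.05  | 0.01  |

The structure encodes the intended physiology: the pain group's power is
dominated by large slow sway (≈4× total band power), while its corrective
activity carries *less* power but sits at *higher* frequency — since path
length scales as ω·a and acceleration as ω²·a, this yields shorter tracks
with higher peak accelerations, and the dominant slow component makes the
pattern elliptical.

Per-subject heterogeneity is two independent lognormal amplitude
multipliers: σ = 0.42 for components below 1 Hz (band power is
slow-dominated and its between-subject coefficient of variation in seated
cohorts is near 1) and σ = 0.15 for faster components (corrective activity,
and hence path length, varies much less). Ellipticity gets additive
Gaussian jitter (SD 0.15, floored at 1). Anthropometry is drawn per sex
from Gaussian models of a mixed adult cohort. Amplitudes were calibrated
once so that *retained* (post-QC) cohorts of 50 + 50 subjects reproduce the
magnitudes the analysis is designed around — healthy ≈ 91 cm track and
0.029 cm² total band power, pain ≈ 0.117 cm² (ratio ≈ 4) — while the raw
(pre-QC) cohorts preserve all four contrast directions. The IQR fence
trims the pain group's slow-sway tail, which widens the track-length gap
and erases most of the acceleration gap in retained cohorts; the
acceleration contrast should therefore be read as a generator-level
property.

Determinism: a master seed spawns per-subject `SeedSequence` children, so
subject k's signal is independent of cohort size, and an identical spec
yields a bit-identical cohort.

Tracks re-enter the pipeline at the raw stage through the exact algebraic
inverse of the CoP formula — the bilinear load distribution
`TL = F/4·(1−u)(1+v)` etc. with `u = x/w`, `v = y/l` — whose channel sum is
the subject's weight force at every sample and whose forward CoP
reproduces the track to machine precision.

### What the generator does not model

Fatigue and other non-stationarity within a trial, sensor calibration
error and drift, load-cell nonlinearity, the correlation between
anthropometry and sway parameters (weight only enters through the force
scale, which the CoP formula cancels), and any realistic class overlap
structure beyond lognormal amplitude spread. Classifier accuracies on
synthetic cohorts (≳95%) are therefore upper bounds that say the protocol
and plumbing are sound — not estimates of clinical separability, which on
real data is far weaker.

## Numerical choices and degenerate inputs

* Zero-phase filtering keeps input length; cutoffs at/above Nyquist raise.
* `compute_cop` raises at the first sample with non-positive total load.
* Band edges outside spectral support clip with a warning; fully outside
  raise.
* Tracks shorter than 2 samples (length), 3 (acceleration), 10
  (ellipticity) raise; a track whose AP velocity never oscillates has no
  movement cycles and raises.
* The IQR fence needs ≥ 4 values; with IQR = 0 only exact matches survive
  (constant data is untouched).
* `ncf.sf` is numerically unreliable at zero noncentrality; power falls
  back to the central F there.
* Problem sizes in the test suite are scaled (20–60 s at 50–200 Hz,
  cohorts of 6–30 per group) except where a check is about study scale,
  which runs the full 60 s / 1 kHz, 50-per-group conditions.

## Known limitations

* The residual-analysis cutoff selector is a standard stand-in; the
  acquisition literature contains several variants and the choice shifts
  acceleration magnitudes (path length and sub-10 Hz band powers are
  insensitive to it).
* Printed band areas in the motivating analyses are unitless; this package
  reports cm², so absolute comparisons carry an unknown scale factor.
* Post-hoc ("observed") power is reported because the reference tables use
  it; it is a deterministic function of F and the dfs, not new evidence.
* No multiple-testing correction is applied across the eight bands, by
  design fidelity to the analysis being reproduced.
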