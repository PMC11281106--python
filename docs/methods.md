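# Methods

`trunksway` analyzes trunk sway recorded by a chest-mounted smartphone during
seated office work, and compares movement variability and complexity between a
pain-free group (PG) and a chronic-spinal-pain group (CSPG). This note
documents the models, the defaults and why they were chosen, what the
synthetic cohort does and does not emulate, and the numerical decisions a
maintainer would want written down.

## Signal chain

1. **Synchronization.** Android sensors start at different times and sample
   irregularly. All streams are cropped to the interval
   `[max(starts), min(stops)]` and each channel is linearly interpolated onto
   a constant 100 Hz axis (integer-nanosecond grid, no extrapolation).
   Quaternions are interpolated componentwise and renormalized; at seated
   sway amplitudes (< 3 degrees) this is indistinguishable from slerp.
2. **Accelerometer preprocessing**, in this order: 4th-order Butterworth
   low-pass at 10 Hz applied forward-backward (zero phase); gravity removal
   by subtracting a 0.3 Hz zero-phase low-pass estimate per axis (tracks slow
   posture drift); mean detrending; 150-sample centered moving average with
   shrinking edge windows (even windows are promoted to the next odd length
   so the filter stays centered). The rotation vector gets a 5-sample moving
   average and renormalization. The order is contractual and guard-tested:
   permuting stages changes the output.
3. **Activity removal.** Non-seated intervals are maximal runs where the
   Euclidean magnitude of the processed accelerometer exceeds 2 m/s^2, each
   dilated by a 0.5 s guard (postural transitions bleed past the strict
   excursion), merged when overlapping. The 2 m/s^2 threshold is derived two
   ways and both round to the same integer: from reference walking
   accelerations at C7 (sqrt(1.02^2 + 1.15^2 + 1.41^2) = 2.086 m/s^2) and by
   inverting the MET regression `MET = 5.289 mag - 8.5548` at 3 METs
   (2.185 m/s^2). Removal indices computed on the accelerometer are applied
   to the rotation vector by identical sample index (both streams run at
   100 Hz). The processing stage on which the threshold is evaluated and the
   guard width are config keys (`threshold_ms2`, `guard_seconds`).
4. **Windowing.** Sessions tile into 15-minute windows; the central window
   and its two neighbours are `Lunch`, earlier windows `AM1..AMk` (AM1
   earliest), later ones `PM1..PMm`. With an even window count the center is
   `floor(n/2)` (deterministic tie-break). Trailing partial windows are
   discarded; sessions need at least three full windows.
5. **COP projection.** Quaternions decompose to intrinsic z-y'-x''
   (yaw-pitch-roll) Euler angles; samples within 0.1 degrees of gimbal lock
   are flagged and excluded. Each angle is median-centered over the cleaned
   session, then projected: `cop_ap = lever * tan(pitch)`,
   `cop_ml = lever * tan(roll)`. The lever arm (chest-to-pivot distance) is
   never measured by the protocol; the default 500 mm is a plausible
   sternum-to-seat moment arm, and **every mm-scale output is conditional on
   it** (config key `lever_mm`). Samples outside the admissible ellipse
   (semi-axes 25 mm AP, 18 mm ML, boundary inclusive) are excised, not
   interpolated; excision keeps only admissible sway but breaks time
   continuity, a caveat that applies to the fractal measures downstream.
   Original-timeline indices ride along so window bookkeeping survives
   excision exactly.

## Variability measures

**Linear.** Per direction: max, min, mean, SD and variance (sample, N-1
denominator), RMS, IQR (linear-interpolation quartiles), zero-lag
autocorrelation (sum of squares, = N RMS^2), and travelled signal distance
(sum of sqrt(1 + dy^2)). Joint sway metrics: shoelace sway area
(0.5 |sum (X_{n+1} Y_n - X_n Y_{n+1})|; the literal signed, un-halved sum is
available with `sway_area_raw=true`), AP/ML/combined sway ranges, sway path,
RMS sway distance, and mean sway velocity = (fs/N) * path (an exact identity
with the path, tested as such).

**MFDFA.** Kantelhardt's formulation on the profile (cumulative sum of the
mean-subtracted series): segments of length s from both ends, per-segment
polynomial detrend, fluctuation function F_q(s), H(q) by least squares of
log F_q on log s. Defaults: q from -5 to 5 in 0.5 steps (the four reported
orders -5, 0, 2, 4.5 are on the grid), 30 linearly spaced scales from 5
samples to N/8, DFA1 (linear detrending), q = 0 via the logarithmic limit.
The detrend order deserves a note: the protocol we follow prints
"a polynomial order of 0.5", which no polynomial has; order 1 is the standard
DFA1 choice and is config-exposed (`mfdfa_detrend_order`). Input integration
is on by default, consistent with the H(2) ~ 1.5 regime the COP series
occupies (Brownian-like displacement). A sweep utility recomputes H(q) at 5,
10, ..., 30 scales to document grid-resolution stability; the 30-scale result
is canonical.

**Singularity spectrum.** alpha = H(q) + q dH/dq (central differences),
f(alpha) = q (alpha - H(q)) + 1. The maximum sits at alpha0 = alpha(q=0);
positive (left) width = alpha0 - min alpha over q > 0, negative (right)
width = max alpha over q < 0 - alpha0, total = their sum exactly. A
non-monotone alpha grid raises a degenerate-spectrum warning and widths fall
back to the extreme values.

*Finite-size bias.* With 5-sample segments, DFA1 residual variances have ~3
degrees of freedom and their negative-order moments are strongly biased;
white noise then shows ~0.3 of spurious spectrum width regardless of series
length. The estimator-validation suite therefore checks the monofractal-width
property at `scale_min=16` (where the width collapses to < 0.1), while H(q)
recovery is validated at the protocol default `scale_min=5`. Reported widths
from the pipeline inherit the protocol default and should be compared only
against values computed the same way.

**Sample entropy.** Richman-Moorman SampEn with Chebyshev distance, tolerance
r * SD (population SD), self-matches excluded, identical template counts at
m and m+1; m = 4 and r = 0.2 by default (r is unstated in the protocol;
0.2 SD is the field standard, config-exposed). Template pairs are counted
with a KD-tree, so full-session series are cheap. A and B counts of zero
raise a distinct undefined-entropy signal rather than returning a number.

**IAAFT surrogates.** Iterated amplitude-adjusted Fourier transform:
alternate imposing the original Fourier amplitudes and rank-remapping onto
the original values, stopping when the rank permutation stabilizes (or at
100 iterations). Every surrogate is an exact permutation of the input values;
the spectrum is preserved to well under 1% relative RMS. The significance
test computes a statistic (H(q=0) and SampEn by default) on the original and
100 surrogates and flags it when the original falls outside the central 95%
percentile interval. Calibration on linear Gaussian AR(1) inputs puts the
empirical type-I error at the nominal 5% within Monte-Carlo error.

## Group statistics

Window-level features are averaged per participant x day x period (AM/PM;
Lunch excluded), giving a 2 x 6 mixed design: between factor group, within
factor "week" (day 1/3/5 x AM/PM — a single 6-level factor, matching the
df = 5 within effects of the reported tables; a crossed day x period variant
is a config switch away). Sums of squares follow the standard mixed-design
decomposition (verified against brute-force enumeration and pingouin);
Mauchly's W and the Greenhouse-Geisser epsilon are computed from the pooled
within-group covariance (SPSS convention), and GG-corrected dfs are applied
to the within effects when Mauchly rejects at 0.05 (`sphericity_correction`:
auto / always / never). Effect sizes are partial eta squared,
SS_effect / (SS_effect + SS_error), categorized small (< 0.06), medium
(0.06-0.14), large (> 0.14) with the brackets taken literally. Shapiro-Wilk
normality screening is advisory only, and no multiple-testing correction is
applied across features by default (a Benjamini-Hochberg option exists but
the reference analysis applies none). Days default to {1, 3, 5}: acquisition
ran five days but all reported tables use those three.

## Synthetic cohort

No recordings from the original protocol are publicly deposited, so the
package ships a generator whose ground truth is known exactly:

- **Sway angles**: pitch/roll series with prescribed scaling exponent
  (`hurst_target`, on the DFA scale where 1.5 is Brownian; values above 1 are
  fBm built from exact-covariance circulant-embedding fGn increments),
  optionally amplitude-modulated by a binomial cascade (`cascade_p`) to widen
  the multifractal spectrum. Angular SD is defined **at the analysis-window
  timescale** (fractal signals have no scale-free SD), and drift slower than
  three window lengths is removed — seated sway is mean-reverting; unbounded
  fBm would exit the 25/18 mm ellipse at session scale.
- **Accelerometer**: gravity rotated into the tilting sensor frame, white
  measurement noise (SD 0.05 m/s^2), and walking bursts: 8 s rotating-
  direction bouts (0.45 Hz) whose magnitude follows a unimodal envelope
  peaking at 8 m/s^2 — each bout is exactly one above-threshold run, each
  axis stays oscillatory, and the burst survives the gravity high-pass and
  150-sample smoothing with ~2.3 m/s^2 of processed magnitude.
- **Magnetometer** at half rate; all streams get uniform +-2 ms timestamp
  jitter and independent start offsets up to 5 s, exercising the
  synchronization stage without being adversarial.
- **Cohort defaults** mirror the study structure: 6 PG + 10 CSPG, days
  {1, 3, 5}, AM/PM periods, with per-participant jitter of the profile
  (Hurst SD 0.04, lognormal 8% on amplitudes). The group contrasts (CSPG
  hurst 1.75 vs 1.55; sd_ap 0.54 vs 0.38 degrees, i.e. ~4.7 vs ~3.3 mm at
  the 500 mm lever) reproduce the *direction* of the reported group effects;
  the magnitudes are stand-ins, not claims — the original effect sizes were
  never published as generative parameters.

What passing tests show: the estimators recover known exponents, widths and
entropies; the pipeline's bookkeeping is exact; and group contrasts of the
injected kind are detected with the right direction and large effect sizes.
What they do not show: anything about muscle activity, heart rate, real
posture idiosyncrasies (chair geometry, clothing shift, fidgeting
distributions), or the magnitude of real-world group differences.

## Problem sizes and numerical choices

Reduced-size study conditions used by the demo, the end-to-end tests and the
acceptance script: 1024-sample windows (10.24 s at 100 Hz), nine windows per
session, smoothing shortened proportionally (15 samples), 20 cohorts of
6 + 10 participants x 3 days. Estimator oracles run at N = 4096 over 20
seeds; surrogate calibration uses AR(1) (phi = 0.6), N = 512, SampEn m = 2
(at m = 4 and that length the statistic is occasionally undefined, which
would invalidate calibration replicates), 100 surrogates, 200 replicates.

Other numerics: duplicate raw timestamps keep the first occurrence;
interpolation never extrapolates; F^2 values are floored at 1e-300 before
q/2 powers; degenerate (all-equal) ANOVA inputs return a flagged table with
np^2 = 0 rather than NaNs propagating; GG epsilon is clipped to
[1/(k-1), 1]; the ellipse boundary is inclusive so the documented 25/18 mm
extremes are retained.

## Known limitations

- All mm-scale quantities scale linearly with the unmeasured lever arm.
- Excising non-seated and out-of-ellipse samples concatenates discontiguous
  segments; fractal measures on heavily excised windows are biased toward
  larger apparent fluctuations at the junctions.
- The Euler sequence / axis mapping (pitch -> AP, roll -> ML) assumes a
  portrait chest mount; both are config-exposed rather than inferred.
- Spectrum widths at |q| = 5 underestimate the asymptotic cascade width
  (the Legendre extremes are reached only as |q| -> infinity).
- The generator's multifractality control (`cascade_p`) is qualitative: it
  widens the spectrum monotonically but the width is not calibrated to a
  closed form when combined with fGn increments.
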