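# Methods

This note documents the measurement model, the conventions the
implementation fixes where the field's usage is ambiguous, the synthetic
cohort generator, and known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Measurement chain

Each trial starts with a quiet-standing phase (≥ 3 s; the default static
window is [0 s, 3 s), the minimum span guaranteed by the acquisition
protocol, overridable per trial via a `phase` column). Calibration runs in
a fixed order, chosen so that the static calibration quantities are
estimated on raw signals:

1. **Gyroscope bias removal** — per-axis mean over the static window,
   subtracted from the full stream.
2. **Gravity alignment** — the mean static acceleration direction defines
   the craniocaudal (CC) axis; its magnitude must lie in [0.8 g, 1.2 g] or
   the sensor is rejected as non-static/miscalibrated. Gravity fixes only
   the vertical, so the horizontal pair is completed by projecting a
   per-site nominal forward axis (default: sensor x) onto the horizontal
   plane (AP) and closing the right-handed triad (ML = CC × AP). The
   rotation is orthonormal with determinant +1 and preserves norms; a
   heading (yaw) offset is unidentifiable from gravity alone and is assumed
   removed by the vendor calibration performed before acquisition.
3. **Gravity removal** — the static-window mean of the CC acceleration is
   subtracted from the CC column only. Mean subtraction rather than a
   hard-coded 9.81 m/s² makes the step robust to residual misalignment.
4. **Low-pass filtering** — second-order Butterworth, 10 Hz for
   accelerations, 6 Hz for angular velocities, applied forward-backward
   (zero phase). The per-stride indices are phase-sensitive, and zero-phase
   filtering is the de-facto standard in gait analysis; a single-pass
   variant is available behind `FilterConfig(zero_phase=False)`.

Internal units are SI throughout (m/s², rad/s); conversions from g or °/s
happen only at the CSV boundary, and the reader refuses files without an
explicit unit declaration because accelerometer export units genuinely vary
between tools.

## Stride segmentation

Mid-swing produces a dominant positive peak in the sagittal-plane (ML-axis)
shank angular velocity. The detector finds these peaks (prominence ≥ 1.0
rad/s, minimum separation 0.6 s — both configurable) and places each stride
boundary at the signal minimum preceding the peak, a terminal-contact
proxy. Consecutive boundaries delimit strides; durations outside a
[0.6 s, 2.5 s] plausibility band are discarded (longest consecutive
plausible run kept). The first and last stride of each leg are flagged
non-steady-state — a deterministic proxy for the walkway's 2 m
acceleration/deceleration sections, which at this population's slow
self-selected speed (~0.79 m/s, stride ≈ 1 m) correspond to roughly one to
two strides. At least 3 steady-state strides are required; otherwise the
trial is flagged unusable and, in the paired analysis, the subject is
excluded pairwise. Upper-body indices are computed on the left-leg stride
grid by default (configurable); the event convention anchoring the
boundaries is itself configurable since different laboratories anchor on
initial versus terminal contact.

## Index conventions

- **nRMS** is the per-stride RMS ratio AP/CC or ML/CC. There is no CC nRMS:
  CC is the normalizer. Per-stride values are averaged across steady-state
  strides (median available via config).
- **iHR** is computed per stride: the demeaned segment is linearly
  resampled to 256 samples so the stride harmonics fall exactly on DFT bins
  (no leakage from non-integer alignment), and "power" is the squared DFT
  amplitude. The intrinsic set is even stride harmonics for AP and CC and
  odd for ML — the established harmonic-ratio convention (a stride contains
  two steps) — with the parity map configurable and recorded. The first 20
  harmonics of each parity set are used (`n_harmonics=20`); when a segment
  supports fewer spectral lines the available ones are used with a warning.
- **LDLJ** is applied per axis (the reported values are per-direction), so
  the vector norm reduces to the absolute value of the scalar axis signal.
  Derivative: central differences; integral: trapezoidal rule; both fixed
  and documented. The segment handed to the jerk integral *includes* the
  closing boundary sample, so its first and last samples sit exactly at
  t₁ and t₂ and the duration equals the stride time — with half-open
  segments the duration term would be short by one sample interval, a ~2 %
  bias on the jerk functional at 128 Hz. LDLJ is invariant to uniform
  amplitude scaling by construction. Note on direction: by the formula,
  *larger* (less negative) values indicate more jerk-laden movement; part
  of the clinical literature verbally states the opposite reading. The
  implementation follows the formula and leaves interpretation to the
  reader.

## Reliability surface

For each of the 15 indices, matched by subject across sessions (row order
irrelevant): Shapiro–Wilk on the paired differences (α = 0.05) gates the
choice between the paired t-test and the Wilcoxon signed-rank test.
Cohen's d = mean(diff)/SD(diff) with a normal-approximation CI. Zero-variance
differences use the degenerate convention p = 1, d = 0 (identical sessions)
or a sign test (constant shift).

The ICC is single-measure from the two-way mean squares. The default form
is **absolute agreement** — ICC(A,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)
— matching the described "two-way mixed-effects model for absolute
agreement"; the classical consistency form ICC(3,1) = (MSR−MSE)/(MSR+(k−1)MSE)
is selectable, and the form used is recorded in every output row.
Confidence limits follow the McGraw–Wong F-distribution constructions; the
implementation is cross-checked in the tests against both direct
mean-squares arithmetic and pingouin.

SEM = SD·√(1−ICC). Which dispersion enters the formula is not standardized;
the default is the pooled SD of test and retest values, with the
test-session SD and the SD of differences selectable — published SEM/MDC
pairs in this literature cannot all be reproduced under any single
convention, so the choice is explicit and recorded. MDC = SEM·1.96·m with
m = 2 (the as-printed convention, default for fidelity to the source
literature) or m = √2 (the conventional MDC95). SEM and MDC confidence
limits are obtained by propagating the ICC confidence limits through the
formulas (higher ICC ⇒ lower SEM). Subgroup analysis applies a two-sided
Mann–Whitney U to per-subject absolute test-retest differences split by a
binary label (e.g. age < 40 vs > 40, sex). α = 0.05 throughout; no
multiplicity correction is applied, matching common practice in this
literature.

## Synthetic cohort generator

The generator's defaults are the study conditions the package targets:
49 subjects, two sessions within one visit, 128 Hz, 3 s static lead-in,
8 strides per bout, stride time ~N(1.27 s, 0.08²) (≈ 1 m strides at
0.79 m/s), index-target means and spreads matching a slow-ambulating
clinical cohort (e.g. pelvis AP nRMS ≈ 0.82, pelvis iHR ≈ 71–78 %).

Upper-body accelerations and pelvis angular velocities are finite sums of
the first 4 stride harmonics — the minimal model under which iHR is exact
and nRMS has a Parseval closed form. Given a target iHR and RMS for an
axis, the two parity sets are scaled so the intrinsic/total power ratio and
the total power match the targets exactly; within each set amplitudes decay
as h^(−γ), and the spectral tilt γ drives the smoothness indices. Harmonics
are kept at ≤ 4 (≲ 3.2 Hz) so the 10 Hz anti-aliasing filter barely touches
them. Shank angular velocity is a periodic template of symmetric Gaussian
bumps (positive mid-swing peak, negative pre-swing trough) whose extremum
times — invariant under zero-phase filtering — provide ground-truth stride
events. Sensor frames are tilted by a known pitch (about-ML) rotation,
default 10° ± 2° per subject, to exercise gravity alignment; yaw is
excluded deliberately (see above). Gyroscope bias, white measurement noise
(σ_acc = 0.03 m/s², σ_gyro = 0.005 rad/s) and a slow stride-phase wobble
(CV 2 %) are added; noise and wobble are disabled for analytic-truth tests.

**Analytic truths are stated on the band-limited signal**: the exact
zero-phase Butterworth gain |H(f)|² at each harmonic frequency is applied
to the amplitudes before computing truth values, because filtering is part
of the specified measurement chain. iHR and nRMS truths are closed-form;
LDLJ truth uses the closed-form jerk integral of the harmonic series with
the amplitude maximum found on a dense (8192-point) grid.

Test-retest dependence: each index-determining target is
mean + between-subject effect + session noise, with variances
icc·σ² and (1−icc)·σ², so the population ICC of each index family is
controlled. `generate_paired_values` exposes the same variance-component
sampling at the index level for reliability-only simulations — this is
what the parameter-recovery tests use at replicate scale (100–200 cohorts
of n = 49), while full-signal cohorts (which cost ~0.1 s per trial) are
used once for end-to-end consistency. Target clipping to physical ranges
(iHR ∈ [5, 99] %) slightly reduces the realized between-subject variance
for families whose targets sit near a bound, so full-signal cohorts honor
the requested ICC approximately, not exactly; the index-level sampler is
exact.

What the generator does *not* emulate: cross-axis correlation of real
accelerations (axes are independent), non-stationarity within a bout
beyond the edge ramps, soft-tissue artifact spectra, turning, and
pathological asymmetries beyond what the harmonic targets encode. Passing
the end-to-end tests therefore demonstrates correctness of the measurement
chain on signals satisfying the model, not clinical validity on real
recordings.

## Numerical choices and degenerate inputs

- Resampling before the DFT is linear interpolation with periodic
  extension; at ≥ 64 samples per stride its harmonic distortion is far
  below the 1-percentage-point accuracy checked in the tests.
- Stride boundaries are integer sample indices; duration quantization
  (±0.5 sample) enters LDLJ via the T³ term and averages out across
  strides.
- Degenerate inputs raise rather than guess: zero CC RMS, identically zero
  jerk segments, zero between-subject variance in the ICC table, constant
  difference vectors in the normality test, unmatched subjects in the
  paired tables.
- ICC at MSE = 0 (perfect agreement) short-circuits to estimate 1 with a
  [1, 1] CI.

## Limitations

- The AP/ML completion after gravity alignment relies on a configured
  forward-axis hint; with heading errors the AP/ML split of the indices
  rotates accordingly (iHR parity is axis-specific, so heading matters).
- The fixed-count steady-state rule (drop one stride per end) approximates
  the 2 m distance-based exclusion without position data; at atypical
  stride lengths the two rules diverge.
- MDC conventions differ across the literature (×2 vs ×√2); results must
  cite the multiplier, which the package records in every output.
- Reported reliability is specific to the short-bout protocol emulated
  here; longer bouts generally shift both index values and their
  reliability.
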