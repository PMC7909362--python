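# Methods

## Measurement model

The heart's electrical activity is summarized as a time-varying 3-D dipole
(heart vector). A 12-lead surface ECG observes linear projections of that
dipole; the Kors regression matrix (embedded as constants in
`vcg_core.KORS_MATRIX`, rows X/Y/Z by columns I, II, V1–V6) inverts the
observation approximately, yielding orthogonal X (leftward), Y (inferior),
Z (posterior) leads. The transform is linear and sample-wise, so all later
vector quantities inherit linearity in the input.

**Beat selection.** Beats annotated ectopic, fusion or artifact are
excluded. Without annotations, R peaks are detected on the vector
magnitude and beats whose X-lead correlation with the median template
falls below 0.8 (`corr_threshold`, dimensionless) are dropped.

**Median beat.** Retained beats are aligned on the sample of maximum
|dV/dt| of the X lead (ties break to the earliest sample; only X is used,
Y and Z follow the X alignment — the "time-coherent" construction). The
window spans 280 ms before to 520 ms after the alignment instant, shrunk
to 35%/80% of the estimated RR when the cycle is shorter, so neighbouring
beats never leak into the median. The per-sample median across beats is
robust to a minority of corrupted beats.

**Origin point.** All heart vectors are measured from the electrically
quiet origin, found by sliding a 20 ms window over the 150 ms preceding
the R peak of the VM signal and minimizing
mean|ΔVM| + 0.5·(max−min) + 0.3·(mean − regional minimum).
The third term matters: the top of a P wave is flat but not quiet, and
without the elevation penalty it can capture the search. The R peak used
here is anchored within ±120 ms of the alignment instant because in paced
beats the global VM maximum can belong to a large T wave. Manual
overrides are accepted and flagged in the output, mirroring practice on
real recordings where a small percentage of origins and fiducials need
correction.

**Fiducials.** QRS onset/offset are the first ≥8 ms runs of the (lightly
smoothed) VM below max(5 µV, 2 × baseline spread, 2% of peak VM) scanning
left/right from the R peak; the relative floor keeps a noisy isoelectric
ST segment below threshold. T offset is the steepest descending tangent
after the T peak intersected with the baseline, carried forward to the
actual sub-threshold return when that comes later; the T-peak search is
bounded by min(600 ms, 0.9·RR) after QRS onset. The tangent construction
systematically ends 10–20 ms before the true end of a smooth T lobe
(which has a long shallow tail); this bias is constant across recordings
and cancels in all paired contrasts. All thresholds are keyword
arguments.

**Vectors and scalars.** Peak vectors are the XYZ sample at maximal VM in
the interval (mV); area vectors are per-axis trapezoidal integrals
(mV·ms), which makes QRS + JT areas exactly additive to the QRST area.
The area SVG is Wilson's ventricular gradient (QRST integral); the peak
SVG is the heart vector at maximal VM over the whole QRST. SAI QRST is
the ℓ1-type rectified integral and iVMQT the ℓ2 (vector-magnitude)
integral, so iVMQT ≤ SAI QRST holds per sample. Azimuth is the (X, Z)
plane angle, 0° at +X, positive toward +Z, range (−180°, 180°]; elevation
is measured from +Y, range [0°, 180°]; a `flip_z` switch serves
anterior-positive dialects. Zero-magnitude vectors report a degenerate
flag rather than a silent 0°. The J point is taken as the QRS offset.

**Memory angles.** The headline memory angle is QRS_DDD-7 vs T_AAI-7 on
peak vectors (area basis is computed in parallel; both are emitted, the
CLI's `--basis` switches the headline). Memory angles are measured on
same-day recordings; the only cross-day angles are the four explicitly
defined comparison angles.

## Circular statistics

Mean direction and resultant length R̄ come from the first trigonometric
moment; circular variance is 1 − R̄ and circular SD √(−2 ln R̄) (degrees).
κ is the ML von Mises concentration (Bessel-ratio inversion with Newton
refinement, no small-n bias correction). The 95% CI of the mean uses the
large-sample circular dispersion for n ≥ 15 and a seeded bootstrap below
that, since the study-scale n = 20 sits near the asymptotic limit. The
circular median minimizes mean circular distance, ties to the smallest
angle. Rayleigh (Z = nR̄² with the standard series p), one- and two-sample
Kuiper (Stephens-corrected asymptotic p) and two-sample Watson U² are all
rotation-invariant; the Watson series is short-circuited to p = 1 at
U² ≈ 0 where it does not converge. Hotelling's paired test forms the
rectangular difference vector per pair and tests it against (0,0) with
F(2, n−2); note it has no power against a pure rotation of a *uniform*
sample, whose difference vectors average to zero — the study's variables
are all strongly non-uniform. Fisher–Lee correlation uses the pairwise
sine products, p by leave-one-out jackknife (a seeded permutation option
exists); the circular–linear correlation uses the
Fisher–Mardia–Jupp R² with the χ²(2) approximation on nR². Correlation
analyses downstream apply a p < 0.001 gate for multiplicity.

## Longitudinal models

Angles enter mixed models on the axial scale t = 2θ + 360° so that the
linear model respects axial topology; every reported coefficient except
the angle-on-angle slope (dimensionless) is halved back to degrees. Day
is coded 0/1 (day 1 → 0), so the day coefficient is the day-1 → day-7
change. Model 1 adjusts for age, female sex, MI history and NSVT history;
Model 2 adds LVEF, diabetes, hypertension, ACEi/ARB and class III
antiarrhythmics. Both adjust for the corresponding QRS variable (azimuth
with azimuth, elevation with elevation, area with area; for QRS outcomes
the pairing flips to the T variable). Clinical covariates enter as main
effects *and* day interactions; the interaction carries the
"modification of the change" reading and is the reported row. Covariates
without variation in a given cohort (a universal history at n = 20) are
dropped with their interactions rather than left collinear.

Fits use statsmodels MixedLM with REML and a random intercept + day
slope (unstructured 2×2 covariance); Wald 95% CIs. With only two
occasions per subject the slope variance is weakly identified, so
singular or non-convergent fits fall back to a random intercept and are
flagged — at study scale roughly half the fits take the fallback, which
is a property of the two-occasion design, not a numerical accident.

The random-slope likelihood-ratio test compares the two covariance
structures at ML, with the boundary 50:50 χ²(1):χ²(2) mixture as
reference. Because two occasions cannot identify a slope variance, the
test's calibration is assessed on a four-occasion balanced design, where
an in-package profiled-ML evaluator (fixed effects profiled out by GLS,
Nelder–Mead over ≤4 log-Cholesky variance parameters, batched per-subject
Cholesky solves) computes both maximized likelihoods quickly and agrees
with MixedLM's ML log-likelihood to numerical precision (asserted in the
suite). At n = 50 subjects its type-I error sits at the nominal 5%.

## Synthetic cohort

The generator emulates the study conditions: 20 patients, four
10-second 500 Hz recordings each, RR ≈ 830 ± 120 ms shared by all four
recordings (the protocol rate-matches), sensed QRS ≈ 111 ms / QT ≈ 407 ms
vs paced ≈ 162 / 465 ms, sensed QRS pointing left and slightly posterior,
paced QRS posterior-superior, baseline sensed T anterior — all with
per-patient jitter. Waveforms are compact smooth lobes: an asymmetric
(steeper-upstroke) lobe for the QRS — a symmetric lobe would tie the
max-|dV/dt| alignment between up- and downstroke and let noise smear the
median beat — a raised-cosine lobe for P and T, plus a small zero-integral
biphasic component orthogonal to the main direction that opens the loop
without moving the area vector. QT is capped at 80% of RR.

Memory is injected by rotating the day-7 sensed T direction toward the
day-7 paced QRS direction by `cm_rotation_deg` (default 60°), multiplied
by an attenuation per positive covariate (defaults: female ×0.2,
MI ×0.6 — the saturation phenomenon), plus N(0, 5°) person scatter; the
day-7 sensed T magnitude grows ×1.4 (×1.3 more with NSVT history), the
day-7 paced T magnitude falls ×0.7. Covariate prevalences follow the
study cohort (MI 75%, NSVT 85%, female 20%, …). Signals are projected to
the 8 independent leads through the Moore–Penrose pseudo-inverse of the
Kors matrix — chosen so transform ∘ projection closes exactly, a modeling
convenience, not a physiological claim — derived limb leads are computed
from I and II, and white noise (default 5 µV) is added per lead.
Electrode placement differences are one rigid lead-field rotation applied
to both day-7 recordings (half-normal, σ = 3°, hard cap 10°): same-day
pairs share placement, cross-day pairs differ by a single bounded
rotation, which is exactly the situation the same-day measurement rule
addresses. Ground truth (vectors, fiducials, applied rotation) is
evaluated from the noise-free dipole with the package's own metric
definitions.

What the generator does **not** model: torso volume-conduction
inhomogeneity (the lead field is exactly the Kors pseudo-inverse, so
transform error present on real ECGs is absent), pacing-spike artifacts,
baseline wander and muscle noise (noise is white), beat-morphology
variability beyond RR jitter, and any dependence of the memory rotation
axis on patient anatomy. Passing recovery tests therefore demonstrate the
correctness of the measurement chain under the stated statistical
structure, not field performance on clinical recordings. A further
geometric consequence: with the default vector placement the memory
rotation expresses mostly in T *elevation*; T azimuth sits near the
±180° seam where the axial transform is discontinuous, so azimuth-change
coefficients are noisy at n = 20 — visible in the worked example.

## Problem sizes and determinism

All randomness flows from seeded `numpy` generators; cohorts use
`SeedSequence.spawn` per patient, so outputs are byte-identical across
runs. The test suite simulates at the study scale (n = 20 cohorts;
calibration at 1000 replicates of n = 50; coefficient recovery at 200
replicates of 200 patients at the table level, where simulating full
ECGs would add nothing to what is being tested). The acceptance script
re-runs the full study in well under a minute.

## Known limitations

* The tangent T-offset is biased ~10–20 ms early on smooth T waves
  (shared by all recordings; cancels in contrasts; QT-level comparisons
  against other software should expect it).
* No QT rate correction is applied: the protocol rate-matches the four
  recordings, so raw QT is comparable within patient.
* The two-occasion design leaves random-slope variances weakly
  identified; fallback flags should be inspected before interpreting
  random-effect estimates (fixed effects are unaffected).
* The origin/fiducial detectors are tuned for median beats of
  paced/sensed morphology at 500 Hz; other beat types (bundle branch
  block, pre-excitation) may need the exposed thresholds adjusted or
  manual overrides.
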