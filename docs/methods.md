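# Methods

## Constitutive model and sign conventions

The heel pad is modelled as a nonlinear Kelvin–Voigt solid: a spring and
dashpot in parallel, with the viscous term scaled by the instantaneous
strain,

    σ(t) = E·ε(t) + η·ε(t)·ε̇(t)

with compressive strain and stress taken **positive**. ε is the change in
pad thickness relative to the primary (first-contact) thickness h0,
dimensionless; σ is heel–ground force over heel contact area, in kPa
(N/cm² × 10, the only unit conversion in the package, centralized in
`mechanics.KPA_PER_N_CM2`); ε̇ is in 1/s, so η carries kPa·s. Under this
convention both moduli are positive for physical tissue. The strain
scaling of the viscous term makes the model's hysteresis vanish at zero
strain, which matches a pad that is stress-free out of contact.

E and η enter linearly, so the fit is ordinary least squares on the
regressor matrix [ε, ε·ε̇] with no intercept, solved by orthogonal
factorization (`numpy.linalg.lstsq`). The fit is **unconstrained**:
negative estimates are possible on pathological data and are flagged
(`negative_param_flag`), never clipped, because clipping at zero would
bias cohort medians upward. Rank deficiency (e.g. ε·ε̇ identically zero,
which makes η unidentifiable) raises an error naming the degenerate
column. Diagnostics: residual sum of squares and R² = 1 − RSS/TSS about
the stress mean.

## Thickness geometry

Three steel balls resting on the force plate define a plane through their
centers, parallel to the plate at height one ball radius. Pad thickness at
a frame is

    min over cloud points of (signed distance to ball-center plane) + ball radius,

the gap between the lowest calcaneus point and the plate surface. The
distance is **signed** along the normal (oriented plate → foot, chosen via
an `up_hint` vector, default lab vertical): a noisy point below the plate
surface yields a negative contribution and a reduced — possibly negative —
thickness, which is reported rather than clamped, so plate penetration is
visible instead of silently inflating the minimum. Thickness is invariant
under rigid motions applied jointly to cloud and balls (property-tested
with random rotations/translations), which is what makes the marker-ball
plane a valid datum regardless of plate tilt. All geometry is in mm.

## Contact frame and primary thickness

The primary thickness is the thickness at the frame where the heel first
touches the plate. Simulated trials carry that frame as an annotation
(`contact_index`), playing the role of the radiographic contact
identification in the original measurement chain; the analysis prefers it
when present. For force-only recordings the fallback is a force-threshold
rule: the first frame where force holds ≥ threshold (default 10 N) for a
configurable number of consecutive frames (default 1). The threshold rule
is necessarily late by a frame or more — force is exactly zero at true
touch-down under this model — which is why the annotation, when available,
is authoritative.

## Strain rate

ε̇ is computed by central finite differences on interior frames and
one-sided differences at the endpoints (`numpy.gradient`), exact for
quadratics on the uniform 50 Hz grid. Optional pre-smoothing of strain
uses a Savitzky–Golay local polynomial (window 5 frames, degree 2),
off by default so noise-free data differentiates exactly; turn it on for
real, noisy thickness channels.

## Hysteresis and EDR

One stance is a single loading/unloading cycle. The cycle is split at the
first global strain maximum (first occurrence on plateaus); the maximal
frame belongs to both branches so the loop polygon is contiguous; a
monotone strain series degenerates to a single-frame unloading branch and
warns. Energy dissipation is the absolute shoelace area of the polygon
(loading up, unloading back, closed by the chord from last to first point
when noisy unloading does not return exactly to the origin). The loading
work is the trapezoid integral of σ dε over the loading branch, and
EDR = 100 · |loop| / loading. For any loop with non-negative stress EDR
lies in [0, 100]; values outside (possible when deep unloading stress goes
negative) are flagged, not clamped. Peak strain and peak stress are taken
as **independent** channel maxima — the viscous term makes stress peak
earlier than strain, so a single "peak point" is not well defined.

## Synthetic cohort

The generator emulates the study conditions: 10 subjects (configurable),
ages uniform on 23–72 y, BMI Normal(24.6, 3.5), both heels measured in
both a rested (time-zero) and a continuously loaded condition, sampled at
50 Hz.

**Population structure.** Subject-level parameters come from a latent
Gaussian regression on standardized age: h0 ~ 15.99 ± 1.8 mm with
R(age, h0) = −0.507; E ~ 192.55 ± 30 kPa (independent of age by default);
η ~ 43.9 ± 13 kPa·s loading on age (R = +0.518) and on the E latent
(R = +0.821); peak strain ~ 0.685 ± 0.02 loading negatively on E
(R = −0.765). The dispersions are chosen so the sampled min–max ranges
match the reported ranges at n = 20 heels. Small multiplicative left/right
jitter (CV 2%) splits the sides; it slightly attenuates heel-level
correlations (by ~3–4%), which the calibration bands absorb. η is floored
at 2 kPa·s against rare negative tail draws.

**Condition effect.** The post-loading heel is the *same* heel with
η multiplied by 20.37/43.9 ≈ 0.464 and h0 by 15.72/15.99 ≈ 0.983 — the two
effects reported as significant. E and peak strain carry over unchanged:
their observed post-loading shifts (to 197.585 kPa and 0.69) were not
significant, so the generator treats them as noise around no effect rather
than imposing a deterministic shift that every paired test would detect.
Consequently the paired Wilcoxon on the sampled parameters reports the
all-ties case for E (p = 1 by convention), the correct "no detectable
change" signature.

**Trajectory.** Stance strain follows a raised cosine up and down —
0 → peak → 0, C¹ at the peak — over a 0.6 s stance (typical at ~1 m/s;
the source reports no duration), with the loading phase taking 0.45 of
stance by default (loading is faster than unloading in gait; a symmetric
`raised_cosine` shape is also available). At 50 Hz this gives 31 frames.
The stress channel is built with the **same finite-difference strain rate
the analysis computes**, not the analytic derivative: the simulator and
analyzer then agree frame-by-frame, and the noiseless round trip recovers
(E, η) to machine precision rather than to O(Δt²) discretization error.
This is a deliberate choice — the generator's job is to exercise the
estimator under controlled truth, and discretization consistency keeps
"truth" well defined at the sampled frames.

**Noise.** Multiplicative Gaussian noise on stress (CV 1% by default)
models the pressure-plate measurement chain; optional additive Gaussian
thickness noise (off by default; 0.05 mm is a reasonable magnitude for
fluoroscopic tracking) models the imaging chain. No noise model is
reported for the original rig; these are assumptions, exposed in
`GaitConfig`.

**Scenes.** The calcaneus is a rigid lower-half ellipsoid shell
(semi-axes 25 × 18 × 20 mm, 200 points), translated vertically each frame
so its lowest point sits exactly at the trial's thickness; ball centers
are three non-collinear points one radius above the plate; an optional
plate tilt rotates everything rigidly. The scenes are geometrically
consistent with the trials by construction, so the geometry path and the
thickness-channel path of the analysis agree to 1e-9 and can be
cross-checked (`heelpad analyze --from-geometry`).

**Heel area** is a scalar channel (default 25 cm², giving peak forces of a
few hundred N); spatial pressure maps are out of scope. Force is
σ·area/10.

**Determinism.** Every draw descends from one integer seed; each heel uses
a substream keyed by (seed, CRC32(subject id), side, condition), so trials
are reproducible individually and cohorts are reproducible as a whole.

## Statistics layer

Observations are heels (left and right pooled, two per subject), matching
the source analysis; `per_subject_mean` averages sides first for users
concerned about intra-subject correlation — neither choice makes the 20
heels truly independent, which is a limitation of the design, not the
implementation. Summaries are median and min–max range. Correlations are
Pearson R with two-sided p from the t transform (n − 2 df); constant
variables are flagged rather than silently NaN. The paired Wilcoxon
signed-rank test drops zero differences, uses the exact null when the
effective n ≤ 25 with no tied |difference| ranks, and otherwise the normal
approximation with continuity and tie-corrected variance (scipy's
implementation; an independent 2ⁿ enumeration oracle checks the exact
branch in the tests). The all-zero-differences case is undefined for the
test and reported as p = 1 in the comparison table. No multiple-testing
correction is applied, matching the source analysis.

## Problem sizes and tolerances

The test-suite and reproduction-script workloads are sized for a laptop
core: 10-subject cohorts (40 trials of 31 frames) for round trips, 500
replicate trials for the noise study, 20 replicate cohorts for
seed-averaged medians, 100 replicate cohorts for the paired-contrast
check, 200 subjects for correlation calibration, and a 10⁵-point dense
quadrature as the EDR oracle. Numerical tolerances: noiseless round-trip
recovery 1e-6 relative (achieved: ~1e-15), geometry identities 1e-9 mm,
oracle equivalences 1e-9 (fit), 1e-12 mm (thickness), 0.5% relative (EDR
quadrature).

## What passing tests do and do not show

The generator produces smooth, single-cycle, rate-consistent trajectories
with well-behaved noise; real recordings have registration error,
non-constant heel area, multi-modal force profiles, frame drops and
soft-tissue artefacts none of which are modelled. Passing the recovery and
calibration tests shows the estimator chain is correct and well
conditioned under the stated model — not that the model captures every
feature of real heel-pad data. Two emergent quantities illustrate the
model dependence: with the default 0.6 s raised-cosine stance, peak
stress (~185 kPa) and EDR (~75%) come out higher than the reported
medians (146 kPa, 22%), because both are strongly rate- and
trajectory-shape-dependent and the true per-frame trajectories are
unavailable for calibration. The calibrated targets (h0, E, η, peak
strain, their correlations and the condition contrast) are
trajectory-independent and are the quantities the pipeline is validated
against.

## Known limitations

- The Kelvin–Voigt form cannot represent stress relaxation at constant
  strain beyond the elastic plateau; alternative constitutive models are
  out of scope.
- Contact-frame detection from force alone is biased late by design;
  supply the annotated contact frame when the imaging chain provides one.
- The statistics layer treats heels as exchangeable observations; no
  mixed-effects modelling of the subject/side nesting is attempted.
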