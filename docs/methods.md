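# Methods

## Coordinate model

Landmark files carry image pixel coordinates (x right, y down). All
geometry runs in a canonical frame with y superior and the lateral
direction +x for every hip; right hips are mirrored about a vertical axis
on the way in. The mirror, a y-flip, is orientation-preserving composed
per side (left: diag(1,−1); right: diag(−1,−1)), so the superior direction
is always the 90° counter-clockwise rotation of the lateral direction and
all signed-angle conventions are side-independent. Because every output is
an angle or a ratio, pixel spacing is carried as metadata but never used.

The pelvic horizontal reference line runs through the caudal teardrop
points of the two hips, directed left-hip → right-hip. A hip's lateral
direction is defined anatomically as *away from the contralateral hip*
(−reference direction for left hips, +reference for right hips), which
makes every measurement exactly equivariant under arbitrary image rotation
— there is no "mostly horizontal" assumption anywhere. With a single hip
and no reference the pipeline assumes an image-horizontal pelvis; callers
can supply an explicit fallback axis instead. Which landmarks define the
pelvic horizontal is a genuine convention choice; teardrop-to-teardrop was
chosen because the caudal teardrop is already required for the
depth-width ratio and is among the most reliably identified pelvic
landmarks.

## Geometric primitives

**Femoral head circle.** Algebraic (Kåsa) least squares on the mean-centered
head-contour landmarks, refined by Levenberg-Marquardt on the orthogonal
distances with tolerances 1e-15; the fit is exact to ~1e-12 on noiseless
circle points for any arc ≥ 60°. Collinearity is detected by a condition
number > 1e12 of the normal equations. All head-contour landmarks enter
the fit; head-neck junction landmarks are excluded because they bias the
radius in cam hips. The rms orthogonal residual is retained as a per-hip
noise estimate (see alpha angle below).

**Head-neck axis.** From the fitted head center through the midpoint of the
narrowest neck cross-section, where cross-sections pair the i-th lateral
with the i-th medial neck landmark. This is deterministic and standard
practice; a single pair degenerates gracefully to that pair's midpoint.

**Shaft axis.** Total-least-squares line through midpoints of paired shaft
landmarks, oriented distally via the proximal → distal landmark ordering.
Fewer than two pairs means too little shaft is depicted; the neck-shaft
angle is then *missing with a reason*, never zero, and downstream report
tables carry the reduced n.

## Measurement conventions

- **Sign conventions.** mAI is positive for an up-sloping roof (lateral
  edge superior to the medial sourcil). WCEA/LCEA are positive lateral to
  the vertical through the head center and negative medial — needed for
  dysplastic hips; the diagnostic thresholds are unaffected.
- **Extrusion index.** The lateral/medial head extremes come from the
  fitted circle rather than raw landmarks, making EI robust to contour
  sampling density; the uncovered width is clamped at 0 when the bony edge
  lies lateral to the head.
- **Alpha angle.** The departure search walks the superior profile (head
  contour then head-neck junction contour) from the point farthest from
  the neck toward the neck, restricted to the superior-lateral sector
  (signed angle from the neck axis in [0°, 105°]). The alpha point is the
  first landmark farther than `r + max(0.01·r, 3·rms)` from the center,
  where rms is the head circle-fit residual. The noise-adaptive term
  matters: with a fixed 1 % tolerance, landmark jitter at or above 0.01·r
  trips spurious departures on the spherical part of nearly every hip and
  the alpha angle degenerates into noise; tying the threshold to the fit
  residual keeps it strictly above the noise floor while reducing exactly
  to the 1 % rule on clean data. If nothing departs, the last junction
  landmark is used (spherical head). Quantization error is bounded by the
  contour spacing. The search is superior-lateral only; on AP films a
  circumferential search would double-count the inferior junction.
- **Triangular index ratio.** The station line is perpendicular to the
  neck axis at 0.5 r from the center. The crossing is found by linear
  interpolation along the piecewise-linear superior profile *including*
  the head contour and the lateral neck edge — for a spherical head the
  crossing lies on the head circle itself (giving TIR = 1), and for short
  junction segments it can lie neckward of them, so restricting the search
  to the junction contour alone would spuriously report the measurement
  missing. TIR is reported as d/r so that TIR > 1 reads "contour outside
  the head circle at the station" (aspherical, cam); the r/d orientation
  is available via `MeasureOptions(tir_orientation="r_over_d")` since both
  readings exist in the literature.
- Missing measurements never abort a hip: `measure_all` records a reason
  per missing value and continues.

## Diagnosis

Boundary inclusivity follows the printed comparator symbols exactly:
≤ / ≥ thresholds are inclusive (ADR ≤ 250, mAI ≥ 13° and ≤ 3°, WCEA ≤ 25°,
LCEA ≥ 40°, EI ≥ 25 %, AA ≥ 60°), the NSA bounds strict (> 140°, < 120°).
A missing measurement yields a missing flag. mAI overcoverage is kept as
its own flag rather than folded into "pincer". A convenience any-of-four
dysplasia flag exists, but the per-measurement flags are primary.

## Agreement statistics

Single-rater ICCs from the two-way ANOVA mean squares; absolute agreement
`(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)` and consistency
`(MSR−MSE)/(MSR+(k−1)MSE)`, with exact F-based 95 % intervals (the
consistency interval from the MSR/MSE F ratio, the absolute-agreement
interval via the Satterthwaite composite). The two-way random and mixed
models share these single-rater formulas; the model label records the
intended inference. Missing values are handled by listwise deletion with
the dropped count reported. Zero total variance leaves the estimate
undefined (reported missing with a reason) rather than raising; the
degenerate MSE = MSC = 0 case (perfect replication of varying subjects) is
reported as ICC 1 with a point interval.

Bland-Altman limits of agreement use the conventional 1.96 multiplier. The
systematic-error rule is |bias| > 2.5° for the angle measurements (mAI,
AA, WCEA, LCEA, NSA) and |bias| > 1 % of the measurement for the ratios
(ADR, EI, TIR), with "1 % of the measurement" interpreted as 1 % of the
grand mean of the pairwise averages (the natural scale estimate for a
paired design; the fraction is a module constant).

Rating bands: ICC poor < 0.50, moderate 0.50–0.75, good 0.76–0.90,
excellent > 0.90; percent agreement poor < 50 %, moderate 50–70 %, good
71–90 %, excellent > 90 %. The printed band edges leave the open intervals
(0.75, 0.76) and (70, 71) unassigned; both are assigned to the higher band.

Sample-size planning uses the Walter–Eliasziw–Donner asymptotic closed
form for testing H0: ICC = ρ₀ against ρ₁ with k replicates, one-sided α by
default (reliability hypotheses are directional), rounded up. For the
reference design ρ₀ = 0.75, ρ₁ = 0.90, k = 2, α = 0.05, β = 0.20 it gives
n = 26; published designs computed from the exact tables land in the same
range (high twenties).

## Synthetic generator

`generate_hip` inverts the measurement definitions: given target values
for AA, WCEA, LCEA, mAI, ADR and NSA it constructs a left hip (head radius
100 px by default) realizing them exactly, mirrors the contralateral side,
and places both teardrops at equal height so the pelvic reference is
exactly horizontal. Key constructions:

- Head contour exactly on the circle; the cam deformity is a radial blend
  beyond the alpha station, `ρ(ψ) = r(1 + 0.015 + 0.45·(α − ψ))` (ψ in
  radians from the neck axis), whose first landmark beyond the station
  already exceeds the departure tolerance — so the measured alpha angle is
  exact up to half the contour spacing (2° landmarks by default).
- Neck and shaft landmark pairs are symmetric about their axes, making the
  recovered axes, and hence NSA, exact.
- The acetabular width-line direction that realizes the target ADR with the
  teardrop at its prescribed height is solved by bracketing root-finding;
  infeasible target combinations (e.g. LCEA < WCEA forcing the bony edge
  medial to the sourcil) raise a construction error.
- EI and TIR are *emergent*: EI follows analytically from the edge
  position and head circle; TIR from the continuous radial profile (circle
  crossing for α ≤ 60°, blend or blend-to-neck connector crossing
  otherwise, including the closed-form `0.5/cos α` value when the crossing
  sits on the radial step at the station). Prescribing them too would
  over-constrain the geometry.

Observer variability is modeled as isotropic Gaussian landmark jitter,
independent per observer × round, deterministic given seeds.
`simulate_study` defaults emulate a 30-radiograph, two-observer, two-round
reliability design with morphology targets drawn uniformly from
general-population ranges (alpha 42–78°, LCEA 18–45°, WCEA a 2–8° margin
below LCEA, mAI −2–14°, ADR 230–330, NSA 115–145°). Jitter magnitudes are
user parameters (default 1.5 px on a 100 px head radius), not estimates of
any particular study's observers.

What the generator does *not* emulate: correlated landmark errors (real
annotation errors are strongly correlated along the contour), statistical
shape variation beyond the parameter targets, projection/tilt effects of
pelvic orientation, and truly aspherical (non-circular) head models.
Passing closure and monotonicity tests therefore demonstrates internal
consistency of the geometry and statistics, not performance on real
radiographs.

## Problem sizes and runtime

Test-suite and acceptance problem sizes were chosen to characterize the
pipeline at desk scale: 100-spec closure sweeps, 50 similarity/mirror
transforms, 100 random 10×2 ICC matrices, and 30-hip studies at jitter
levels {0, 1, 2, 4, 8} px. The full suite runs in well under a minute on a
single CPU; `scripts/acceptance.py` in a few seconds.

## Known limitations

- The default 80-point schema is a reasonable construction, not a published
  annotation protocol; real deployments should supply their protocol's
  role map as a schema YAML.
- The alpha angle is quantized by the contour spacing and, like all
  circle-fit-dependent measurements, is the most noise-sensitive output —
  consistent with the reliability ordering reported for such pipelines.
- Diagnosis from a single AP view is inherently partial; several
  morphological diagnoses require additional radiographic views, which are
  out of scope.
- The absolute-agreement ≤ consistency ICC ordering is a theorem only when
  the between-rater mean square exceeds the error mean square; with
  pure-noise rater columns the sampled ordering can flip.
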