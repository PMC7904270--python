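# Methods

This note documents the models implemented in `gazekit`, the choices made
where the published description leaves latitude, the synthetic study
conditions, and what the tests do and do not demonstrate.

## Eye ROI extraction

The eye boxes are computed literally from the 68-landmark scheme (origin
top-left): the horizontal extent runs between the outer/inner corner
x-coordinates, the vertical extent between the upper-lid minimum and
lower-lid maximum with a fixed ±3 px margin. The margins are applied in
original-image pixels, before magnification; whether they should scale
with resolution is unspecified, so they are kept fixed as printed. The
crop is converted to grayscale with BT.601 luma weights (the source is
silent on the colorimetric convention), magnified ×2 with bilinear
interpolation (nearest/bicubic selectable via `interp_order`), and eroded
with a 1-pixel-radius disk element, interpreted as the 3×3 cross — the
smallest Euclidean disk and the common morphology default. Erosion is a
running minimum, so it darkens isolated bright speckle (specular dots)
without moving the dark iris; the property tests assert it never
increases a pixel.

A point found in ROI coordinates maps back to the full image as
`origin + p/scale`. The ×2 resampling introduces a half-pixel-scale
offset between the two frames; the round-trip contract is therefore
0.5 px, which is below the integer-grid resolution of the localizer.

## Snakuscule iris localization

The probe is an inner disk of radius `r` and an annulus out to `βr`,
scored by `G = mean(annulus) − mean(disk)` and maximized. Two details
are deliberate and fixed:

* **Area-normalized difference.** Using region *means* rather than sums
  makes G independent of the annulus/disk area ratio (hence of β except
  through which pixels it admits) and invariant under adding a constant
  to the image; it scales linearly with pixel-value scaling. Both
  invariances are property-tested.
* **Pixel-center membership.** A pixel belongs to disk or annulus by the
  Euclidean distance of its center to the probe center, with no
  fractional border weighting. This keeps the integer-grid scan exactly
  reproducible by a brute-force oracle, which the acceptance suite
  exploits (exact argmax agreement on random images).

The radius comes from anatomy, `r = round(αN)` (half-up), defaulting to
α = 0.25: the iris radius is nearly a biological constant (~7 mm) while
the ROI width tracks the eyeball diameter (~25 mm). The rough scan
evaluates integer x in `[⌈βr⌉, ⌊N−βr⌋]` on the centerline `y = ⌊M/2⌋`;
since pixel indices are 0-based the range is additionally intersected
with the positions where the outer circle lies wholly inside
(`x ≤ N−1−⌊βr⌋` etc.), which trims at most one endpoint. Refinement
evaluates the `(2δ+1)²` integer candidates around the rough center,
clipping candidates whose probe would leave the image. Tie-breaks are
fixed: smallest x on the scan; nearest-to-rough, then row-major, on
refinement. Defaults α = 0.25, β = 1.4, δ = 2 are the published sweep
optimum; sweep grids (α step 0.01 over 0.21–0.25, β 1.32–1.52 step 0.04,
δ 1–4) are exposed in `sweep_iris_parameters`.

Out-of-bounds probes raise rather than truncate. Consequently the method
requires `M ≥ 2⌊βr⌋+2`: very wide-and-short eye crops (high-resolution
imagery, where the fixed +3 px margins are proportionally small) cannot
host the default probe, and callers must supply a taller crop or a
smaller β. At webcam scale (iris radius ≈ 4–5 px) the margins make the
ROI proportionally taller and the probe fits. Sub-pixel centers are not
estimated; the printed procedure is integer-grid, so the floor on
localization error is the rounding distance (≤ ~0.7 px).

## Anchor point and eye vectors

The anchor is the arithmetic mean of the 36 stable landmarks — all 68
minus the 12 eye and 20 mouth points (68 − 12 − 20 = 36), which move
with eye rotation and articulation. Averaging 36 points suppresses
individual landmark jitter by ~1/6 and the anchor remains defined under
partial occlusion. It is translation- and rotation-equivariant with the
landmark cloud (tested). The subset is configurable. Eye vectors are raw
pixel differences iris − anchor, both in full-image coordinates;
inter-ocular normalization is deliberately not applied (the mapping is
person-specific and fitted per session).

## Head pose

Pose uses six landmarks (chin 9, nose tip 31, outer eye corners 37/46,
mouth corners 49/55) against a fixed generic rigid face model
(millimetres, nose tip at origin, bilaterally symmetric; the exact
coordinates are documented constants in `headpose.py` — no published 3D
model exists for this pipeline, and all round-trip tests project this
same template, so the specific values cannot silently bias results).
The camera, when uncalibrated, uses the standard webcam approximation
f = image width, principal point = image center, zero distortion.

The estimator minimizes the sum of squared reprojection errors with
Levenberg–Marquardt (scipy `least_squares`), initialized from a
scale/centroid estimate at identity rotation, with four ±25° rotated
restarts as local-minimum guards; the contract is the
reprojection-minimum property (RMSE at the estimate ≤ RMSE at the truth
on synthetic data), not the solver identity. Angles are intrinsic
pitch(x)–yaw(y)–roll(z) Euler angles, camera x right / y down /
z forward, in degrees — degrees because they feed the mapping
polynomials directly and coefficient magnitudes stay interpretable.
Collinear landmark configurations are rejected up front (second singular
value test). Round trips over |pitch|, |yaw| ≤ 30°, |roll| ≤ 20° at
600 mm recover angles to < 0.5° (in practice ~1e-13, i.e. exactly, on
noise-free projections).

## Mapping functions and fusion

One polynomial per eye and per screen axis over
`(e_h, e_v, h_p, h_y, h_r)`. The six presets are nested term sets:

| No. | terms |
|-----|-------|
| 1 | 1, e_h, e_v |
| 2 | 1, e_h, e_v, e_h·e_v, e_h², e_v² |
| 3 | No.1 + h_p, h_y, h_r |
| 4 | No.2 + h_p, h_y, h_r |
| 5 | No.3 + h_p², h_y², h_r² |
| 6 | No.4 + h_p², h_y², h_r² |

The published table of term sets is not available in the extracted text;
these definitions follow its prose description (No.1/2 eye-only linear
and squared terms; No.3–6 mix in head pose), keep the presets nested so
model-selection comparisons are meaningful, and are configurable as
explicit term lists, so any alternative reading is one config line.
Defaults: preset 4 horizontally, preset 2 vertically (the published
per-axis optima; head-pose terms help horizontally but not vertically,
plausibly because the anchor-referenced eye vector already carries
vertical head information).

Fitting is ordinary least squares via SVD, with rank checking that names
the collinear terms (e.g. all calibration frames at one gaze point) and
residual-RMS/condition-number diagnostics stored with the model. The
calibration protocol takes the *first* `n_calib` detected frames
(default 1000) — the published protocol, matching an online calibration
phase — with a seeded random-split mode behind a flag for robustness
checks only.

Fusion is the convex combination `g_f = w·left + (1−w)·right`, default
w = 0.5 ("for simplicity"; the published per-axis optima are 0.5 H /
0.6 V, and a per-axis `w_v` override exists). Endpoints w = 1 / w = 0
reproduce the single-eye predictions bit-for-bit. When one eye is
flagged unavailable the weight collapses to the other, with a log note.

## Evaluation metrics

* Normalized iris error `e = max(d_left, d_right)/d`; invariant under
  similarity transforms of all four points (property-tested with 1000
  random transforms); `e ≤ 0.05` is the benchmark threshold.
* Angular errors: true and estimated gaze rays run from the 3D eyeball
  center to the 3D screen points; H and V are absolute azimuth and
  elevation differences of the rays in the camera frame (azimuth in the
  x–z plane, elevation against it, y down ⇒ positive elevation is up),
  C = √(H²+V²). The published table note calling C "the sum of the
  squares" is corrected to the root-sum-square: every printed H/V/C
  triple satisfies it to printed precision (max deviation ~0.11°, within
  one-decimal rounding propagation), which the benchmark-table tests
  verify. L errors use the left eyeball as vertex, R the right; the
  fused POR uses the midpoint of the two eyeball centers (the published
  convention mentions both eyeballs without specifying the combination;
  the midpoint is the symmetric choice).
* Reports round to one decimal degree; CSVs keep full precision. DF/TF
  (detected/total frames) bookkeeping is recomputed from the frame
  table.

## Synthetic study conditions

`fixtures` generates three kinds of data; all randomness flows from one
seed per spec and fixed seeds give bit-identical output.

**Eye ROIs.** A hard-edged dark disk (default 60×48 px, radius 15 =
0.25 × width, iris level 60 on sclera 200) with optional top-band eyelid
occlusion (skin level 150), specular dot, Gaussian noise, and an
optional 1-px anti-aliased rim (default off so energies are analytically
checkable). The 60×48 geometry keeps the default probe
(⌊βr⌋ = 21 px) inside the image everywhere on the centerline. The seeded
benchmark (`random_eye_specs`) jitters the center sub-pixel
(x ∈ [23, 37], y ∈ [22, 26] — real ROI construction keeps the iris near
the centerline) and the intensity levels; the radius stays at the
anatomical 0.25 ratio the α prior encodes, since that ratio *is* the
stated study condition. Under these conditions clean localization is
within 1 px always (the residual is pure integer-grid rounding, ≤0.7 px)
and σ = 8 noise with 20% eyelid occlusion stays within 2 px in ≥95% of
200 seeded draws. What this does **not** show: robustness to glasses
reflections, off-axis gaze ellipticity, soft iris boundaries or landmark
error in the ROI placement — real-image performance rests on the
published dataset results, not on these fixtures.

**Face landmarks.** A generic 68-point 3D template (embedding the
six-point pose model exactly) projected through the pinhole camera at a
chosen pose. Used as ground truth for pose round trips; it contains no
landmark-detector noise model.

**Gaze sessions.** Eye vectors are generated in *mapping space*: targets
are drawn uniformly on a 430×270 mm screen (camera at the screen's top
center, eyes 600 mm away and ±32 mm off-axis), the head follows slow
sinusoidal pitch/yaw/roll sweeps (±10/15/5°, incommensurate periods),
and per frame the ground-truth polynomials (linear-dominant, documented
in `fixtures.py`) are inverted for `(e_h, e_v)` by a vectorized Newton
solve (residual < 1e-10), after which Gaussian pixel noise is added.
Because the forward model is the same polynomial family the fit
estimates, zero-noise coefficient recovery is exact (≤1e-10 relative)
and zero-noise session errors are numerically zero — this validates the
fitting/evaluation machinery, *not* the adequacy of polynomial mapping
for real eyes. The noisy condition uses σ = 1.0 px on eye vectors,
chosen once as a realistic iris-localization jitter at webcam resolution
(iris radius ≈ 4.5 px); with independent symmetric per-eye noise the
fused POR (w = 0.5) averages it down by ~1/√2, and over 20 seeds the
fused mean C (~0.73°) beats the better single eye (~0.98°). Default
session sizes are 1000 calibration + 500 test frames, matching the
published first-1000-frames protocol at a desk-scale test length.

## Numerical choices and degenerate inputs

* `round(αN)` uses half-up rounding (platform-stable).
* Energy raises on out-of-bounds probes; scans/refinement clip their
  candidate sets instead and raise only when nothing remains.
* Rank-deficient calibration designs and sessions with fewer than
  `n_calib + 1` usable frames raise with counts; undetected frames
  count toward TF only.
* Mapping inversion in the session generator refuses locally
  non-invertible coefficient sets (singular Jacobian) rather than
  returning spurious eye vectors.
* Reference-table consistency tolerances reflect printed precision: one
  decimal ⇒ up to ~0.12° propagated deviation for the RSS identity,
  0.1 for recomputed column means.

## Known limitations

* Landmark detection is not included; accuracy on real video inherits
  whatever detector supplies the CSVs.
* The snakuscule is integer-grid; sub-pixel iris localization is out of
  scope by design.
* The default probe does not fit very wide-and-short eye crops (see
  above); β or the crop height must be adapted at high resolutions.
* The generic face model is not person-specific; absolute head-pose
  angles on real faces carry a model-mismatch bias that the synthetic
  round trips cannot expose (the mapping functions only require pose
  *consistency*, not anatomical truth).
* Reproducing the published absolute errors requires the GI4E/EYEDIAP
  datasets; the reference tables are retained only for arithmetic
  self-consistency checks.
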