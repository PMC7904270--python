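# gazekit

Feature-based gaze tracking for a single camera under natural light.

Remote eye trackers built on infrared illumination are accurate but
sensitive to ambient light and glasses; plain webcams are everywhere but
give low-resolution eye images in which classic pupil detectors break
down. `gazekit` implements a regression-based pipeline that works from a
single RGB frame plus a 68-point facial-landmark annotation:

1. **Eye ROI extraction** — rectangular eye regions bounded by the twelve
   eye landmarks (left eye: `X_l = P43.x`, `X_r = P46.x`,
   `Y_t = min(P44.y, P45.y) − 3`, `Y_b = max(P47.y, P48.y) + 3`; right eye
   analogous with 37/40, 38/39, 41/42), magnified ×2 and cleaned with a
   grayscale erosion (1-px disk element).
2. **Iris-center localization** — a *snakuscule*, a circular probe with an
   inner disk (radius *r*) and outer annulus (radius *βr*), scored by the
   gray difference `G(p) = mean(annulus) − mean(disk)`. Instead of
   evolving the contour, the radius is fixed from eye anatomy
   (`r = round(αN)` with α ≈ 0.25, since iris radius ≈ 7 mm against an
   eyeball diameter ≈ 25 mm tracked by the ROI width *N*), scanned along
   the horizontal centerline, then refined over a `(2δ+1)×(2δ+1)`
   candidate grid. Defaults `α = 0.25, β = 1.4, δ = 2`.
3. **Anchor point** — the mean of the 36 stable landmarks (jaw, brows,
   nose; the mouth and eye landmarks vibrate with articulation and eye
   rotation). The **eye vector** `e = (e_h, e_v)` is iris center minus
   anchor.
4. **Head pose** — pitch/yaw/roll from six landmarks (chin 9, nose tip
   31, eye corners 37/46, mouth corners 49/55) by iterative 2D–3D
   reprojection minimization against a generic rigid face model.
5. **Gaze mapping** — per eye and per screen axis, a low-order polynomial
   `g = Σ_k c_k · t_k(e_h, e_v, h_p, h_y, h_r)` fitted by least squares
   during a calibration phase (first 1000 detected frames of a session).
   Six nested term-set presets are provided; No. 4 (quadratic eye terms +
   linear head terms) is the default horizontally, No. 2 (quadratic eye
   terms only) vertically.
6. **Binocular fusion** — `g_f = w·g_left + (1−w)·g_right` with
   `w = 0.5` by default; `w = 1` / `w = 0` reproduce the single-eye
   pipelines exactly.

Accuracy is reported as the normalized iris-center error
`e = max(d_left, d_right)/d` (with `e ≤ 0.05` ≈ "inside the pupil" as the
benchmark) and as horizontal/vertical/combined angular gaze errors
`H, V, C = √(H²+V²)` in degrees measured from the 3D eyeball center.

The package ships synthetic generators (eye ROIs with eyelid occlusion
and noise, a projectable 68-point face template, simulated
calibration/test gaze sessions with known ground-truth coefficients) so
the entire pipeline is testable without any dataset download. Landmark
*detection* is out of scope: all entry points accept precomputed
landmark CSVs.

## Worked example

Simulate a noisy gaze session (1000 calibration + 500 test frames, 1 px
eye-vector noise), then run the calibration/test protocol:

```sh
gazekit simulate --seed 3 --n-calib 1000 --n-test 500 --noise 1.0 --out demo_sess
gazekit evaluate --session demo_sess --n-calib 1000 --report demo_report
```

prints (degrees, rounded to report precision):

```json
{
  "H_L": 0.7, "V_L": 0.5, "C_L": 1.0,
  "H_R": 0.8, "V_R": 0.6, "C_R": 1.1,
  "H_F": 0.5, "V_F": 0.4, "C_F": 0.7
}
```

The left eye alone lands ~1.0° off the target, the right ~1.1°; fusing
the two PORs with `w = 0.5` averages out the independent per-eye noise
and brings the combined error down to 0.7°. `demo_report/` also contains
the full per-frame error table (`frame_errors.csv`) and an unrounded
summary with TF/DF bookkeeping (`summary.json`).

The same protocol is available as a library:

```python
import gazekit as gk

session = gk.simulate_session(gk.SyntheticSessionSpec(pixel_noise_sigma=1.0, seed=3))
report = gk.evaluate_session(session, gk.EvalConfig(n_calib=1000, w=0.5))
print(report.summary())          # rounded means, as above
```

Other commands: `gazekit locate-iris` (full-image iris centers from a
PNG + landmark CSV), `gazekit head-pose`, `gazekit calibrate` /
`gazekit track` (fit and apply mapping models), `gazekit sweep-iris` and
`gazekit sweep-w` (parameter grids).

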