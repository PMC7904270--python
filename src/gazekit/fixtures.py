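"""Synthetic data generators: eye ROIs, face landmarks, gaze sessions.

Everything downstream of this module is testable without any dataset
download:

* :func:`render_eye_roi` draws a dark iris disk on a lighter sclera with
  optional eyelid occlusion, specular dot and Gaussian noise -- a stand-in
  for real eye crops. The default geometry keeps iris_radius / width near
  0.25 (the anatomical iris-to-eyeball ratio the localizer's alpha prior
  encodes) and leaves the ROI tall enough that the default snakuscule
  probe fits everywhere on the centerline.
* :func:`render_face_landmarks` projects a generic rigid 68-point 3D face
  template through a pinhole camera at a given pose, providing ground
  truth for head-pose round trips.
* :func:`simulate_session` builds calibration/test gaze sessions whose eye
  vectors are generated in *mapping space*: screen targets are drawn
  uniformly on the screen and the eye vectors are solved from known
  ground-truth mapping coefficients (same polynomial family as the fitted
  models), so coefficient recovery is an exact check. 3D eyeball and
  screen-target coordinates are recorded for angular-error evaluation.

All randomness flows from the single seed in each spec; fixed seed means
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .evaluation import GazeFrame, GazeSession, ScreenGeometry, por_to_screen_3d
from .face_features import EyeROI, LandmarkSet
from .gaze import PRESETS, TERM_EXPONENTS, EyeVector, _resolve_terms
from .headpose import CameraModel, HeadPose, default_face_model, project_points

__all__ = [
    "SyntheticEyeSpec",
    "SyntheticSessionSpec",
    "EyePairSample",
    "render_eye_roi",
    "eye_roi_from_image",
    "random_eye_specs",
    "render_eye_pair",
    "default_face_template_68",
    "render_face_landmarks",
    "default_true_coeffs",
    "simulate_session",
]


# ---------------------------------------------------------------------------
# Synthetic eye ROIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticEyeSpec:
    """Parameters of one synthetic eye ROI.

    Defaults: a 60x48 px ROI with a radius-15 iris (radius/width = 0.25)
    centered in the image; hard-edged disk, no occlusion, no noise.
    """

    width: int = 60
    height: int = 48
    true_center: tuple[float, float] = (30.0, 24.0)
    iris_radius: float = 15.0
    sclera_level: float = 200.0
    iris_level: float = 60.0
    eyelid_cover_fraction: float = 0.0
    eyelid_level: float = 150.0
    noise_sigma: float = 0.0
    specular_dot: bool = False
    antialias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.iris_level < self.sclera_level <= 255:
            raise ValidationError(
                "need 0 <= iris_level < sclera_level <= 255, got "
                f"{self.iris_level}, {self.sclera_level}"
            )
        if not 0 < self.iris_radius < self.width / 2:
            raise ValidationError(
                f"iris_radius must lie in (0, width/2), got {self.iris_radius}"
            )
        x, y = self.true_center
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise ValidationError(f"true_center {self.true_center} outside image")
        if not 0 <= self.eyelid_cover_fraction <= 1:
            raise ValidationError("eyelid_cover_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def render_eye_roi(spec: SyntheticEyeSpec) -> tuple[np.ndarray, tuple[float, float]]:
    """Render the eye ROI of ``spec``; returns (uint8 image, true center).

    The iris is a hard-edged disk (pixel-center membership), optionally
    with a 1-px linearly blended rim when ``antialias`` is set. The eyelid
    is a full-width band overwriting the top ``eyelid_cover_fraction`` of
    the iris (and the sclera above it). Noise is Gaussian, then clipped to
    [0, 255]. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.true_center
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    dist = np.hypot(xx - cx, yy - cy)
    img = np.full((spec.height, spec.width), spec.sclera_level, dtype=float)
    if spec.antialias:
        # 1-px linear rim between iris and sclera
        t = np.clip(dist - (spec.iris_radius - 0.5), 0.0, 1.0)
        img = spec.iris_level + (spec.sclera_level - spec.iris_level) * t
    else:
        img[dist <= spec.iris_radius] = spec.iris_level
    if spec.eyelid_cover_fraction > 0:
        lid_bottom = cy - spec.iris_radius + spec.eyelid_cover_fraction * 2 * spec.iris_radius
        img[yy < lid_bottom] = spec.eyelid_level
    if spec.specular_dot:
        dot = np.hypot(xx - (cx + spec.iris_radius / 3), yy - (cy - spec.iris_radius / 3))
        img[dot <= 1.5] = 250.0
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), (float(cx), float(cy))


def eye_roi_from_image(image: np.ndarray, side: str = "left") -> EyeROI:
    """Wrap a rendered ROI image as an :class:`EyeROI` at scale 1, origin 0.

    With scale 1 and a zero origin, ROI coordinates equal full-image
    coordinates, so localization results compare directly to the
    generator's true center.
    """
    return EyeROI(image=np.asarray(image, float), side=side, origin=(0.0, 0.0), scale=1)


def random_eye_specs(
    n: int,
    seed: int = 0,
    noise_sigma: float = 0.0,
    eyelid_cover_fraction: float = 0.0,
) -> list[SyntheticEyeSpec]:
    """A seeded benchmark of n randomized eye specs.

    The iris center jitters horizontally over the scan range and a couple
    of pixels vertically (the ROI construction from eyelid landmarks keeps
    real irises near the centerline); sclera and iris levels vary over
    plausible ranges. The iris radius stays at the anatomical ratio of
    0.25 x width that the localizer's alpha prior encodes.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        specs.append(
            SyntheticEyeSpec(
                true_center=(
                    float(rng.uniform(23, 37)),
                    float(rng.uniform(22, 26)),
                ),
                iris_radius=15.0,
                sclera_level=float(rng.uniform(180, 220)),
                iris_level=float(rng.uniform(40, 80)),
                eyelid_cover_fraction=eyelid_cover_fraction,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


@dataclass(frozen=True)
class EyePairSample:
    """A left/right ROI pair with ground truth in a shared image frame."""

    roi_left: EyeROI
    roi_right: EyeROI
    gt_left: tuple[float, float]
    gt_right: tuple[float, float]

    @property
    def interocular(self) -> float:
        return float(np.hypot(self.gt_right[0] - self.gt_left[0],
                              self.gt_right[1] - self.gt_left[1]))


def render_eye_pair(
    spec_left: SyntheticEyeSpec,
    spec_right: SyntheticEyeSpec,
    interocular_px: float = 60.0,
) -> EyePairSample:
    """Render two ROIs placed so the true centers are ``interocular_px`` apart."""
    img_l, tc_l = render_eye_roi(spec_left)
    img_r, tc_r = render_eye_roi(spec_right)
    roi_l = eye_roi_from_image(img_l, side="left")
    origin_r = (interocular_px + tc_l[0] - tc_r[0], tc_l[1] - tc_r[1])
    roi_r = EyeROI(image=np.asarray(img_r, float), side="right", origin=origin_r, scale=1)
    gt_l = tc_l
    gt_r = (interocular_px + tc_l[0], tc_l[1])
    return EyePairSample(roi_left=roi_l, roi_right=roi_r, gt_left=gt_l, gt_right=gt_r)


# ---------------------------------------------------------------------------
# 68-point face template and landmark rendering
# ---------------------------------------------------------------------------

def default_face_template_68() -> np.ndarray:
    """A generic rigid 68-point 3D face template (mm), nose tip at origin.

    Camera frame at identity pose: x right, y down, z away from the
    camera. The template embeds the six-point pose model exactly at
    indices 9, 31, 37, 46, 49 and 55, and is bilaterally symmetric.
    """
    pts = np.zeros((68, 3))

    def put(i: int, x: float, y: float, z: float) -> None:
        pts[i - 1] = (x, y, z)

    # jaw 1-17: half-ellipse from image-left jaw over the chin to image-right
    for k in range(17):
        ang = np.pi * k / 16.0
        put(k + 1, -70.0 * np.cos(ang), -10.0 + 75.0 * np.sin(ang), 40.0 - 30.0 * np.sin(ang))
    # brows 18-27
    for k, x in enumerate((-55.0, -45.0, -35.0, -25.0, -15.0)):
        put(18 + k, x, -45.0, 25.0)
        put(27 - k, -x, -45.0, 25.0)
    # nose bridge 28-31 and base 32-36
    for k, (y, z) in enumerate(((-35.0, 18.0), (-24.0, 12.0), (-12.0, 6.0), (0.0, 0.0))):
        put(28 + k, 0.0, y, z)
    for k, x in enumerate((-15.0, -8.0, 0.0, 8.0, 15.0)):
        put(32 + k, x, 12.0, 8.0)
    # eyes 37-42 (image left) and 43-48 (image right)
    right_eye = [
        (-45.0, -35.0, 20.0),
        (-38.0, -39.0, 18.0),
        (-27.0, -39.0, 18.0),
        (-20.0, -35.0, 18.0),
        (-27.0, -31.0, 18.0),
        (-38.0, -31.0, 18.0),
    ]
    for k, (x, y, z) in enumerate(right_eye):
        put(37 + k, x, y, z)
        # mirror for 43-48: preserve corner ordering (43 inner, 46 outer)
    left_eye = [(-x, y, z) for (x, y, z) in right_eye]
    order = [3, 2, 1, 0, 5, 4]  # mirrored sequence keeps 43=inner, 46=outer
    for k, idx in enumerate(order):
        put(43 + k, *left_eye[idx])
    # mouth outer 49-60
    outer = [
        (-28.0, 35.0, 12.0),
        (-18.0, 30.0, 11.0),
        (-9.0, 28.0, 10.0),
        (0.0, 28.0, 10.0),
        (9.0, 28.0, 10.0),
        (18.0, 30.0, 11.0),
        (28.0, 35.0, 12.0),
        (18.0, 41.0, 11.0),
        (9.0, 43.0, 10.0),
        (0.0, 43.0, 10.0),
        (-9.0, 43.0, 10.0),
        (-18.0, 41.0, 11.0),
    ]
    for k, (x, y, z) in enumerate(outer):
        put(49 + k, x, y, z)
    # mouth inner 61-68
    inner = [
        (-20.0, 35.0, 13.0),
        (-9.0, 33.0, 12.0),
        (0.0, 33.0, 12.0),
        (9.0, 33.0, 12.0),
        (20.0, 35.0, 13.0),
        (9.0, 38.0, 12.0),
        (0.0, 38.0, 12.0),
        (-9.0, 38.0, 12.0),
    ]
    for k, (x, y, z) in enumerate(inner):
        put(61 + k, x, y, z)

    # consistency with the six-point pose model
    for idx, xyz in default_face_model().items():
        pts[idx - 1] = xyz
    return pts


def render_face_landmarks(
    pose: HeadPose,
    camera: CameraModel | None = None,
    template_3d: np.ndarray | None = None,
) -> LandmarkSet:
    """Project the 68-point template at ``pose``; ground truth for pose tests.

    Raises :class:`ValidationError` when any template point ends up at or
    behind the camera (e.g. zero translation depth).
    """
    if camera is None:
        camera = CameraModel.default(640, 480)
    if template_3d is None:
        template_3d = default_face_template_68()
    projected = project_points(
        template_3d, pose.rotation(), np.asarray(pose.translation, float), camera
    )
    return LandmarkSet(projected)


# ---------------------------------------------------------------------------
# Simulated gaze sessions
# ---------------------------------------------------------------------------

#: Ground-truth mapping coefficients (mm screen units per px / per degree):
#: linear-dominant so the forward map is invertible over the screen.
_TRUE_COEFFS_H = {
    "1": 215.0, "eh": 10.0, "ev": 0.5, "eh*ev": 0.02, "eh^2": 0.05, "ev^2": 0.02,
    "hp": 0.3, "hy": 1.2, "hr": 0.2, "hp^2": 0.01, "hy^2": 0.02, "hr^2": 0.005,
}
_TRUE_COEFFS_V = {
    "1": 135.0, "eh": 0.4, "ev": 8.0, "eh*ev": 0.02, "eh^2": 0.02, "ev^2": 0.06,
    "hp": 1.0, "hy": 0.3, "hr": 0.2, "hp^2": 0.02, "hy^2": 0.01, "hr^2": 0.005,
}


def default_true_coeffs(
    preset: int | Sequence[str], axis: str, eye: str = "left"
) -> np.ndarray:
    """Ground-truth coefficients for a preset/axis/eye (right eye perturbed)."""
    terms = _resolve_terms(preset)
    base = _TRUE_COEFFS_H if axis == "h" else _TRUE_COEFFS_V
    coeffs = np.array([base[t] for t in terms])
    if eye == "right":
        scale = np.where(np.array(terms) == "1", 1.0, 1.05)
        coeffs = coeffs * scale
    return coeffs


@dataclass(frozen=True)
class SyntheticSessionSpec:
    """Parameters of a simulated calibration/test gaze session.

    The default screen is 430 x 270 mm (a typical desktop monitor) mounted
    with the camera at its top center; the eyes sit 600 mm away, 32 mm
    either side of the mid-line. Head pose follows slow sinusoidal
    pitch/yaw/roll sweeps of +-10/15/5 degrees unless a trajectory is
    given. ``pixel_noise_sigma`` is added to the solved eye vectors.
    """

    n_calib_frames: int = 1000
    n_test_frames: int = 500
    screen_size: tuple[float, float] = (430.0, 270.0)
    eyeball_left: tuple[float, float, float] = (32.0, 0.0, 600.0)
    eyeball_right: tuple[float, float, float] = (-32.0, 0.0, 600.0)
    preset_h: int | tuple[str, ...] = 4
    preset_v: int | tuple[str, ...] = 2
    coeffs: dict | None = None  # {(eye, axis): array}; None -> defaults
    head_pose_trajectory: np.ndarray | None = None  # (n, 3) degrees
    head_amplitudes: tuple[float, float, float] = (10.0, 15.0, 5.0)
    pixel_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_calib_frames < 1 or self.n_test_frames < 1:
            raise ValidationError("need at least one calibration and one test frame")
        n_terms = max(
            len(_resolve_terms(self.preset_h)), len(_resolve_terms(self.preset_v))
        )
        if self.n_calib_frames < n_terms:
            raise ValidationError(
                f"n_calib_frames={self.n_calib_frames} < {n_terms} mapping terms"
            )
        if self.screen_size[0] <= 0 or self.screen_size[1] <= 0:
            raise ValidationError("screen_size must be positive")
        if self.pixel_noise_sigma < 0:
            raise ValidationError("pixel_noise_sigma must be >= 0")

    def resolved_coeffs(self) -> dict[tuple[str, str], np.ndarray]:
        out: dict[tuple[str, str], np.ndarray] = {}
        for eye in ("left", "right"):
            for axis, preset in (("h", self.preset_h), ("v", self.preset_v)):
                key = (eye, axis)
                if self.coeffs is not None and key in self.coeffs:
                    c = np.asarray(self.coeffs[key], float)
                    n_terms = len(_resolve_terms(preset))
                    if c.shape != (n_terms,):
                        raise ValidationError(
                            f"coefficients for {key} must have {n_terms} entries, "
                            f"got {c.shape}"
                        )
                    out[key] = c
                else:
                    out[key] = default_true_coeffs(preset, axis, eye)
        return out

    def geometry(self) -> ScreenGeometry:
        w, h = self.screen_size
        return ScreenGeometry(
            origin=(-w / 2.0, 30.0, 0.0),  # camera at screen top center
            x_axis=(1.0, 0.0, 0.0),
            y_axis=(0.0, 1.0, 0.0),
            mm_per_unit=1.0,
            size=(w, h),
        )


def _forward_terms(terms: Sequence[str], coeffs: np.ndarray, head: np.ndarray):
    """Closure computing (value, d/d_eh, d/d_ev) of the polynomial, vectorized."""
    hp, hy, hr = head[:, 0], head[:, 1], head[:, 2]
    parts = []
    for c, t in zip(coeffs, terms):
        i, j, a, b, s = TERM_EXPONENTS[t]
        parts.append((float(c), i, j, (hp**a) * (hy**b) * (hr**s)))

    def f(eh: np.ndarray, ev: np.ndarray):
        val = np.zeros_like(eh)
        d_eh = np.zeros_like(eh)
        d_ev = np.zeros_like(eh)
        for c, i, j, hfac in parts:
            base = c * hfac
            val = val + base * eh**i * ev**j
            if i:
                d_eh = d_eh + base * i * eh ** (i - 1) * ev**j
            if j:
                d_ev = d_ev + base * j * eh**i * ev ** (j - 1)
        return val, d_eh, d_ev

    return f


def _invert_mapping(
    terms_h, coeffs_h, terms_v, coeffs_v, gh, gv, head, tol=1e-10, max_iter=80
) -> tuple[np.ndarray, np.ndarray]:
    """Solve (e_h, e_v) with F_h(e)=gh, F_v(e)=gv by vectorized Newton."""
    f_h = _forward_terms(terms_h, coeffs_h, head)
    f_v = _forward_terms(terms_v, coeffs_v, head)
    eh = np.zeros_like(gh)
    ev = np.zeros_like(gv)
    for _ in range(max_iter):
        vh, dh_eh, dh_ev = f_h(eh, ev)
        vv, dv_eh, dv_ev = f_v(eh, ev)
        r1, r2 = vh - gh, vv - gv
        if max(np.abs(r1).max(), np.abs(r2).max()) < tol:
            break
        det = dh_eh * dv_ev - dh_ev * dv_eh
        if np.any(np.abs(det) < 1e-12):
            raise ValidationError(
                "ground-truth mapping is locally non-invertible (singular Jacobian); "
                "the coefficient set is underdetermined for session simulation"
            )
        eh = eh - (dv_ev * r1 - dh_ev * r2) / det
        ev = ev - (-dv_eh * r1 + dh_eh * r2) / det
    else:
        raise ValidationError("mapping inversion did not converge; check coefficients")
    return eh, ev


def simulate_session(spec: SyntheticSessionSpec) -> GazeSession:
    """Simulate a gaze session with known ground-truth mapping coefficients.

    Targets are drawn uniformly on the screen; per frame and per eye the
    eye vectors are solved from the ground-truth polynomials given the
    head pose, then pixel noise is added. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_calib_frames + spec.n_test_frames
    w, h = spec.screen_size
    targets = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])

    if spec.head_pose_trajectory is not None:
        head = np.asarray(spec.head_pose_trajectory, float)
        if head.shape != (n, 3):
            raise ValidationError(
                f"head_pose_trajectory must have shape ({n}, 3), got {head.shape}"
            )
    else:
        t = np.arange(n)
        ap, ay, ar = spec.head_amplitudes
        head = np.column_stack(
            [
                ap * np.sin(2 * np.pi * t / 313.0),
                ay * np.sin(2 * np.pi * t / 457.0 + 1.0),
                ar * np.sin(2 * np.pi * t / 211.0 + 2.0),
            ]
        )

    coeffs = spec.resolved_coeffs()
    terms_h = _resolve_terms(spec.preset_h)
    terms_v = _resolve_terms(spec.preset_v)
    geometry = spec.geometry()

    vectors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for eye in ("left", "right"):
        eh, ev = _invert_mapping(
            terms_h,
            coeffs[(eye, "h")],
            terms_v,
            coeffs[(eye, "v")],
            targets[:, 0],
            targets[:, 1],
            head,
        )
        if spec.pixel_noise_sigma > 0:
            eh = eh + rng.normal(0.0, spec.pixel_noise_sigma, n)
            ev = ev + rng.normal(0.0, spec.pixel_noise_sigma, n)
        vectors[eye] = (eh, ev)

    frames = []
    for k in range(n):
        target_3d = por_to_screen_3d(targets[k], geometry)
        frames.append(
            GazeFrame(
                frame_id=f"{k:06d}",
                detected=True,
                target_screen=(float(targets[k, 0]), float(targets[k, 1])),
                target_3d=tuple(float(v) for v in target_3d),
                eyeball_left=spec.eyeball_left,
                eyeball_right=spec.eyeball_right,
                eye_left=EyeVector(float(vectors["left"][0][k]), float(vectors["left"][1][k]), "left"),
                eye_right=EyeVector(float(vectors["right"][0][k]), float(vectors["right"][1][k]), "right"),
                head=HeadPose(float(head[k, 0]), float(head[k, 1]), float(head[k, 2])),
            )
        )
    return GazeSession(
        frames=frames,
        geometry=geometry,
        camera=CameraModel.default(640, 480),
        name=f"synthetic-seed{spec.seed}",
    )
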