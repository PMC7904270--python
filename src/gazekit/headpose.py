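"""Head-pose estimation from six facial landmarks by 2D-3D correspondence.

The six landmarks are the chin (9), nose tip (31), the outer eye corners
(37, 46) and the mouth corners (49, 55). A fixed generic rigid face model
gives their 3D positions in millimetres; the pose is the rotation and
translation minimizing the sum of squared reprojection errors under a
pinhole camera.

Conventions
-----------
Camera frame: x right, y down, z forward (into the scene); the face sits
at positive z. Euler angles are intrinsic pitch(x)-yaw(y)-roll(z), in
degrees, extracted from the rotation matrix; at identity the face looks
straight at the camera. When the camera is uncalibrated the standard
webcam approximation is used: focal length = image width, principal point
= image center, zero distortion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import EstimationError, ValidationError
from .face_features import LandmarkSet

__all__ = [
    "CameraModel",
    "HeadPose",
    "POSE_LANDMARKS",
    "default_face_model",
    "project_points",
    "estimate_head_pose",
]

#: 1-based landmark indices used for pose: chin, nose tip, eye corners, mouth corners.
POSE_LANDMARKS: tuple[int, ...] = (9, 31, 37, 46, 49, 55)

#: Generic rigid face model (mm), camera frame at identity pose: x right,
#: y down, z away from the camera. Nose tip at the origin; the other points
#: lie behind it (larger z). Bilaterally symmetric about x = 0.
_FACE_MODEL_6PT = {
    9: (0.0, 65.0, 10.0),     # chin
    31: (0.0, 0.0, 0.0),      # nose tip
    37: (-45.0, -35.0, 20.0), # outer corner, image-left eye
    46: (45.0, -35.0, 20.0),  # outer corner, image-right eye
    49: (-28.0, 35.0, 12.0),  # mouth corner, image left
    55: (28.0, 35.0, 12.0),   # mouth corner, image right
}

_EULER_SEQ = "XYZ"  # intrinsic pitch(x) - yaw(y) - roll(z)


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: focal length and principal point in pixels."""

    f: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValidationError(f"focal length must be positive, got {self.f}")

    @classmethod
    def default(cls, width: int, height: int) -> "CameraModel":
        """Uncalibrated-webcam approximation: f = width, pp = image center."""
        return cls(f=float(width), cx=width / 2.0, cy=height / 2.0)


@dataclass(frozen=True)
class HeadPose:
    """Pitch/yaw/roll in degrees plus translation (mm) and fit RMSE (px)."""

    pitch: float
    yaw: float
    roll: float
    translation: tuple[float, float, float] = (0.0, 0.0, 600.0)
    rmse: float = 0.0

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.pitch, self.yaw, self.roll])

    def rotation(self) -> Rotation:
        return Rotation.from_euler(_EULER_SEQ, self.angles, degrees=True)


def default_face_model() -> dict[int, np.ndarray]:
    """The six 3D model points (mm), keyed by 1-based landmark index."""
    return {k: np.array(v) for k, v in _FACE_MODEL_6PT.items()}


def project_points(
    points_3d: np.ndarray,
    rotation: Rotation,
    translation: np.ndarray,
    camera: CameraModel,
) -> np.ndarray:
    """Project model points through rotation/translation and the pinhole camera.

    Raises :class:`ValidationError` if any transformed point has z <= 0
    (behind or in the plane of the camera).
    """
    pts = np.asarray(points_3d, dtype=float).reshape(-1, 3)
    cam = rotation.apply(pts) + np.asarray(translation, dtype=float)
    z = cam[:, 2]
    if np.any(z <= 0):
        raise ValidationError("points at or behind the camera (z <= 0)")
    u = camera.f * cam[:, 0] / z + camera.cx
    v = camera.f * cam[:, 1] / z + camera.cy
    return np.column_stack([u, v])


def _pose_residual(
    params: np.ndarray, model: np.ndarray, observed: np.ndarray, camera: CameraModel
) -> np.ndarray:
    rot = Rotation.from_rotvec(params[:3])
    cam = rot.apply(model) + params[3:6]
    z = cam[:, 2]
    if np.any(z <= 1e-6):
        return np.full(observed.size, 1e6)
    u = camera.f * cam[:, 0] / z + camera.cx
    v = camera.f * cam[:, 1] / z + camera.cy
    return (np.column_stack([u, v]) - observed).ravel()


def _initial_translation(
    model: np.ndarray, observed: np.ndarray, camera: CameraModel
) -> np.ndarray:
    """Depth from the scale ratio, x/y from back-projecting the centroid."""
    span_3d = np.linalg.norm(model.max(axis=0)[:2] - model.min(axis=0)[:2])
    span_2d = np.linalg.norm(observed.max(axis=0) - observed.min(axis=0))
    z0 = camera.f * span_3d / max(span_2d, 1e-6)
    cx, cy = observed.mean(axis=0)
    t0 = np.array([(cx - camera.cx) * z0 / camera.f, (cy - camera.cy) * z0 / camera.f, z0])
    return t0 - model.mean(axis=0)


def estimate_head_pose(
    landmarks: LandmarkSet,
    camera: CameraModel,
    model: dict[int, np.ndarray] | None = None,
) -> HeadPose:
    """Estimate pitch/yaw/roll and translation from the six pose landmarks.

    Iterative nonlinear least squares on the reprojection error,
    initialized from a direct scale/centroid estimate; a few rotated
    restarts guard against local minima at large poses. Deterministic for
    fixed input.
    """
    if model is None:
        model = default_face_model()
    try:
        observed = np.array([landmarks.point(i) for i in POSE_LANDMARKS], dtype=float)
        model_pts = np.array([model[i] for i in POSE_LANDMARKS], dtype=float)
    except KeyError as exc:
        raise EstimationError(f"face model missing landmark {exc}") from None

    centered = observed - observed.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise EstimationError(
            "the six pose landmarks are (near-)collinear in the image; "
            f"singular values {sv[:2]}"
        )

    t0 = _initial_translation(model_pts, observed, camera)
    restarts = [np.zeros(3)]
    for axis in (0, 1):
        for sign in (1.0, -1.0):
            rv = np.zeros(3)
            rv[axis] = sign * np.deg2rad(25.0)
            restarts.append(rv)

    best = None
    for rv0 in restarts:
        try:
            sol = least_squares(
                _pose_residual,
                np.concatenate([rv0, t0]),
                args=(model_pts, observed, camera),
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:  # pragma: no cover - solver failure on one restart
            continue
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or rmse < best[0]:
            best = (rmse, sol.x)
        if rmse < 1e-6:
            break
    if best is None:
        raise EstimationError("head-pose optimization failed from every start")

    rmse, params = best
    rot = Rotation.from_rotvec(params[:3])
    pitch, yaw, roll = rot.as_euler(_EULER_SEQ, degrees=True)
    return HeadPose(
        pitch=float(pitch),
        yaw=float(yaw),
        roll=float(roll),
        translation=tuple(float(v) for v in params[3:6]),
        rmse=rmse,
    )
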