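"""Evaluation metrics, gaze sessions, the calibration/test protocol and sweeps.

Metrics
-------
* Normalized iris-center error: ``e = max(d_left, d_right) / d`` where
  d_left/d_right are the Euclidean distances between estimated and labelled
  iris centers per eye and d is the labelled inter-center distance;
  ``e <= 0.05`` (roughly "inside the pupil") is the standard benchmark.
* Angular gaze errors: with the eyeball center as vertex, the true and
  estimated gaze rays are decomposed into azimuth/elevation in the camera
  frame; H and V are the absolute azimuth and elevation differences in
  degrees and C = sqrt(H^2 + V^2) is the combined error.

Protocol
--------
A session is an ordered list of frames. The first ``n_calib`` *detected*
frames (default 1000) calibrate the per-eye horizontal/vertical mapping
functions; the remaining detected frames are the test set. Per test frame
the left (w=1), right (w=0) and fused PORs are evaluated against the 3D
screen target: L errors use the left eyeball center, R the right, and the
fused POR the midpoint of the two. Undetected frames count toward TF
(total frames) but not DF (detected frames).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import EvaluationError, ValidationError
from .face_features import (
    AnchorPoint,
    LandmarkSet,
    compute_anchor,
    extract_eye_roi,
)
from .gaze import (
    DEFAULT_PRESET_H,
    DEFAULT_PRESET_V,
    EyeVector,
    MappingModel,
    eye_vector,
    fit_mapping,
    fuse_por,
    predict_por,
)
from .headpose import CameraModel, HeadPose, estimate_head_pose
from .iris import locate_iris

__all__ = [
    "ScreenGeometry",
    "GazeFrame",
    "GazeSession",
    "ErrorReport",
    "EvalConfig",
    "normalized_error",
    "angular_errors",
    "por_to_screen_3d",
    "screen_3d_to_por",
    "compute_frame_features",
    "evaluate_session",
    "sweep_iris_parameters",
    "sweep_fusion_weight",
    "write_session",
    "read_session",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_BETA_GRID",
    "DEFAULT_DELTA_GRID",
    "DEFAULT_W_GRID",
]

logger = logging.getLogger(__name__)

#: Default sweep grids. The alpha step is 0.01 (the printed step of 0.05
#: cannot produce a 0.21..0.25 grid and is treated as a typo).
DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.21, 0.22, 0.23, 0.24, 0.25)
DEFAULT_BETA_GRID: tuple[float, ...] = (1.32, 1.36, 1.40, 1.44, 1.48, 1.52)
DEFAULT_DELTA_GRID: tuple[int, ...] = (1, 2, 3, 4)
DEFAULT_W_GRID: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def normalized_error(
    est_left: Sequence[float],
    est_right: Sequence[float],
    gt_left: Sequence[float],
    gt_right: Sequence[float],
) -> float:
    """Worst-eye localization distance over the inter-center distance."""
    el, er = np.asarray(est_left, float), np.asarray(est_right, float)
    gl, gr = np.asarray(gt_left, float), np.asarray(gt_right, float)
    d = float(np.linalg.norm(gl - gr))
    if d == 0:
        raise ValidationError("ground-truth iris centers coincide (d = 0)")
    d_left = float(np.linalg.norm(el - gl))
    d_right = float(np.linalg.norm(er - gr))
    return max(d_left, d_right) / d


def _azimuth_elevation(v: np.ndarray) -> tuple[float, float]:
    """Azimuth/elevation (degrees) of a direction in the camera frame.

    Camera x right, y down, z forward: azimuth is the signed angle in the
    x-z plane, elevation the signed angle above it (positive = up).
    """
    az = np.degrees(np.arctan2(v[0], v[2]))
    el = np.degrees(np.arctan2(-v[1], np.hypot(v[0], v[2])))
    return float(az), float(el)


def angular_errors(
    eyeball_3d: Sequence[float],
    target_3d: Sequence[float],
    estimate_3d: Sequence[float],
) -> tuple[float, float, float]:
    """Horizontal, vertical and combined angular errors (degrees).

    The gaze rays run from the eyeball center to the true and estimated
    3D screen points; C = sqrt(H^2 + V^2).
    """
    eye = np.asarray(eyeball_3d, float)
    v_true = np.asarray(target_3d, float) - eye
    v_est = np.asarray(estimate_3d, float) - eye
    for v, name in ((v_true, "target"), (v_est, "estimate")):
        if np.linalg.norm(v) == 0:
            raise ValidationError(f"{name} coincides with the eyeball center")
    az_t, el_t = _azimuth_elevation(v_true)
    az_e, el_e = _azimuth_elevation(v_est)
    daz = abs((az_e - az_t + 180.0) % 360.0 - 180.0)
    H = daz
    V = abs(el_e - el_t)
    return H, V, float(np.hypot(H, V))


# ---------------------------------------------------------------------------
# Screen geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenGeometry:
    """Affine embedding of 2D screen coordinates into the 3D camera frame.

    Screen point (g_h, g_v) maps to
    ``origin + mm_per_unit * (g_h * x_axis + g_v * y_axis)`` (mm).
    """

    origin: tuple[float, float, float]
    x_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    y_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    mm_per_unit: float = 1.0
    size: tuple[float, float] | None = None  # screen extent in screen units

    def __post_init__(self) -> None:
        for name in ("x_axis", "y_axis"):
            v = np.asarray(getattr(self, name), float)
            if np.linalg.norm(v) == 0:
                raise ValidationError(f"{name} must be non-zero")
        if self.mm_per_unit <= 0:
            raise ValidationError("mm_per_unit must be positive")

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "x_axis": list(self.x_axis),
            "y_axis": list(self.y_axis),
            "mm_per_unit": self.mm_per_unit,
            "size": None if self.size is None else list(self.size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        return cls(
            origin=tuple(d["origin"]),
            x_axis=tuple(d["x_axis"]),
            y_axis=tuple(d["y_axis"]),
            mm_per_unit=float(d["mm_per_unit"]),
            size=None if d.get("size") is None else tuple(d["size"]),
        )


def por_to_screen_3d(
    por: Sequence[float], geometry: ScreenGeometry | None
) -> np.ndarray:
    """Map a 2D POR to its 3D point on the screen plane (mm, camera frame)."""
    if geometry is None:
        raise ValidationError("screen geometry is required to place a POR in 3D")
    gh, gv = float(por[0]), float(por[1])
    return (
        np.asarray(geometry.origin, float)
        + geometry.mm_per_unit * (gh * np.asarray(geometry.x_axis, float))
        + geometry.mm_per_unit * (gv * np.asarray(geometry.y_axis, float))
    )


def screen_3d_to_por(
    point_3d: Sequence[float], geometry: ScreenGeometry
) -> tuple[float, float]:
    """Inverse of :func:`por_to_screen_3d` (least-squares onto the plane)."""
    A = np.column_stack(
        [np.asarray(geometry.x_axis, float), np.asarray(geometry.y_axis, float)]
    ) * geometry.mm_per_unit
    b = np.asarray(point_3d, float) - np.asarray(geometry.origin, float)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(sol[0]), float(sol[1])


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------

@dataclass
class GazeFrame:
    """One frame of a gaze session.

    Frames either carry precomputed features (eye vectors + head pose, the
    synthetic-session path) or landmarks from which the image pipeline can
    derive them when an image provider is configured.
    """

    frame_id: str
    detected: bool = True
    target_screen: tuple[float, float] | None = None
    target_3d: tuple[float, float, float] | None = None
    eyeball_left: tuple[float, float, float] | None = None
    eyeball_right: tuple[float, float, float] | None = None
    eye_left: EyeVector | None = None
    eye_right: EyeVector | None = None
    head: HeadPose | None = None
    landmarks: LandmarkSet | None = None

    @property
    def usable(self) -> bool:
        """Detected with a valid target and both eye vectors present."""
        return (
            self.detected
            and self.target_screen is not None
            and self.eye_left is not None
            and self.eye_right is not None
        )


@dataclass
class GazeSession:
    """Ordered frames plus screen geometry and camera model."""

    frames: list[GazeFrame]
    geometry: ScreenGeometry | None = None
    camera: CameraModel | None = None
    name: str = "session"

    @property
    def tf(self) -> int:
        """Total frames."""
        return len(self.frames)

    @property
    def df(self) -> int:
        """Detected frames."""
        return sum(1 for f in self.frames if f.detected)

    @property
    def detection_rate(self) -> float:
        return self.df / self.tf if self.tf else float("nan")


@dataclass
class EvalConfig:
    """Knobs of the session evaluation protocol."""

    n_calib: int = 1000
    preset_h: int | Sequence[str] = DEFAULT_PRESET_H
    preset_v: int | Sequence[str] = DEFAULT_PRESET_V
    w: float = 0.5
    w_v: float | None = None
    alpha: float = 0.25
    beta: float = 1.4
    delta: int = 2
    random_split: bool = False  # robustness-check mode; default = first-N protocol
    split_seed: int = 0
    image_provider: Callable[[str], np.ndarray] | None = None


@dataclass
class ErrorReport:
    """Per-frame and mean H/V/C errors for left, right and fused PORs."""

    frame_table: pd.DataFrame
    means: dict[str, float]
    tf: int
    df: int
    n_calib_used: int
    n_test: int
    config: EvalConfig
    models: dict[str, MappingModel] = field(default_factory=dict)

    @property
    def detection_rate(self) -> float:
        return self.df / self.tf if self.tf else float("nan")

    def summary(self, decimals: int = 1) -> dict[str, float]:
        """Means rounded to report precision (one decimal degree)."""
        return {k: round(v, decimals) for k, v in self.means.items()}


def compute_frame_features(
    image: np.ndarray,
    landmarks: LandmarkSet,
    camera: CameraModel,
    *,
    alpha: float = 0.25,
    beta: float = 1.4,
    delta: int = 2,
) -> tuple[EyeVector, EyeVector, HeadPose, AnchorPoint]:
    """Full per-frame image pipeline: ROIs -> iris -> anchor -> eye vectors -> pose."""
    anchor = compute_anchor(landmarks)
    vectors = {}
    for side in ("left", "right"):
        roi = extract_eye_roi(image, landmarks, side)
        result = locate_iris(roi, alpha=alpha, beta=beta, delta=delta)
        vectors[side] = eye_vector(result, anchor, side=side)
    head = estimate_head_pose(landmarks, camera)
    return vectors["left"], vectors["right"], head, anchor


def _ensure_features(session: GazeSession, config: EvalConfig) -> None:
    """Fill missing per-frame features through the image pipeline if possible."""
    if config.image_provider is None:
        return
    camera = session.camera
    for frame in session.frames:
        if not frame.detected or frame.usable or frame.landmarks is None:
            continue
        image = config.image_provider(frame.frame_id)
        cam = camera or CameraModel.default(image.shape[1], image.shape[0])
        el, er, head, _ = compute_frame_features(
            image,
            frame.landmarks,
            cam,
            alpha=config.alpha,
            beta=config.beta,
            delta=config.delta,
        )
        frame.eye_left, frame.eye_right, frame.head = el, er, head


def evaluate_session(session: GazeSession, config: EvalConfig | None = None) -> ErrorReport:
    """Run the calibration/test protocol on a session and report H/V/C errors.

    The first ``n_calib`` detected frames calibrate four mapping functions
    (left/right x horizontal/vertical); every remaining detected frame is
    evaluated with the left (w=1), right (w=0) and fused (configured w)
    PORs against the 3D target.
    """
    if config is None:
        config = EvalConfig()
    _ensure_features(session, config)
    usable = [f for f in session.frames if f.usable]
    if len(usable) < config.n_calib + 1:
        raise EvaluationError(
            f"need at least n_calib+1 = {config.n_calib + 1} usable frames, "
            f"got {len(usable)} (TF={session.tf}, DF={session.df})"
        )
    if config.random_split:
        rng = np.random.default_rng(config.split_seed)
        order = rng.permutation(len(usable))
        calib = [usable[i] for i in sorted(order[: config.n_calib])]
        test = [usable[i] for i in sorted(order[config.n_calib :])]
    else:
        calib = usable[: config.n_calib]
        test = usable[config.n_calib :]

    models: dict[str, MappingModel] = {}
    for eye_attr, eye_key in (("eye_left", "left"), ("eye_right", "right")):
        frames = [(getattr(f, eye_attr), f.head) for f in calib]
        for axis, preset, col in (
            ("h", config.preset_h, 0),
            ("v", config.preset_v, 1),
        ):
            targets = [f.target_screen[col] for f in calib]
            models[f"{eye_key}_{axis}"] = fit_mapping(frames, targets, preset, axis)

    rows = []
    for f in test:
        por_l = predict_por(models["left_h"], models["left_v"], f.eye_left, f.head)
        por_r = predict_por(models["right_h"], models["right_v"], f.eye_right, f.head)
        por_f = fuse_por(por_l, por_r, w=config.w, w_v=config.w_v)
        row: dict[str, object] = {"frame_id": f.frame_id}
        if f.target_3d is not None and session.geometry is not None:
            eyeballs = {
                "L": f.eyeball_left,
                "R": f.eyeball_right,
            }
            if f.eyeball_left is not None and f.eyeball_right is not None:
                eyeballs["F"] = tuple(
                    (np.asarray(f.eyeball_left) + np.asarray(f.eyeball_right)) / 2.0
                )
            else:
                eyeballs["F"] = f.eyeball_left or f.eyeball_right
            for label, por in (("L", por_l), ("R", por_r), ("F", por_f)):
                eyeball = eyeballs[label]
                if eyeball is None:
                    continue
                est_3d = por_to_screen_3d(por, session.geometry)
                H, V, C = angular_errors(eyeball, f.target_3d, est_3d)
                row[f"H_{label}"], row[f"V_{label}"], row[f"C_{label}"] = H, V, C
        for label, por in (("L", por_l), ("R", por_r), ("F", por_f)):
            row[f"gh_{label}"], row[f"gv_{label}"] = por
        rows.append(row)

    table = pd.DataFrame(rows)
    means: dict[str, float] = {}
    for label in ("L", "R", "F"):
        for comp in ("H", "V", "C"):
            col = f"{comp}_{label}"
            if col in table.columns:
                means[col] = float(table[col].mean())
    logger.info(
        "session %s: TF=%d DF=%d (%.1f%%), calib=%d, test=%d",
        session.name,
        session.tf,
        session.df,
        100 * session.detection_rate,
        len(calib),
        len(test),
    )
    return ErrorReport(
        frame_table=table,
        means=means,
        tf=session.tf,
        df=session.df,
        n_calib_used=len(calib),
        n_test=len(test),
        config=config,
        models=models,
    )


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def sweep_iris_parameters(
    benchmark,
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    betas: Sequence[float] = DEFAULT_BETA_GRID,
    deltas: Sequence[int] = DEFAULT_DELTA_GRID,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Grid sweep of (alpha, beta, delta) on an iris benchmark.

    ``benchmark`` is a sequence of eye-pair samples (left/right ROI with
    ground-truth full-image centers, e.g. from
    :func:`gazekit.fixtures.render_eye_pair`). For every grid point the
    count and rate of pairs with normalized error ``e <= threshold`` is
    tabulated.
    """
    rows = []
    for alpha in alphas:
        for beta in betas:
            for delta in deltas:
                count = 0
                for pair in benchmark:
                    res_l = locate_iris(pair.roi_left, alpha=alpha, beta=beta, delta=delta)
                    res_r = locate_iris(pair.roi_right, alpha=alpha, beta=beta, delta=delta)
                    e = normalized_error(
                        res_l.center_image,
                        res_r.center_image,
                        pair.gt_left,
                        pair.gt_right,
                    )
                    if e <= threshold:
                        count += 1
                rows.append(
                    {
                        "alpha": alpha,
                        "beta": beta,
                        "delta": delta,
                        "count": count,
                        "rate": count / len(benchmark) if len(benchmark) else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def sweep_fusion_weight(
    session: GazeSession,
    ws: Sequence[float] = DEFAULT_W_GRID,
    config: EvalConfig | None = None,
) -> pd.DataFrame:
    """Mean H/V/C of the fused POR for each fusion weight w."""
    base = config or EvalConfig()
    rows = []
    for w in ws:
        report = evaluate_session(session, replace(base, w=w, w_v=None))
        rows.append(
            {
                "w": w,
                "H": report.means.get("H_F", np.nan),
                "V": report.means.get("V_F", np.nan),
                "C": report.means.get("C_F", np.nan),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Session I/O (native CSV + JSON metadata)
# ---------------------------------------------------------------------------

_FRAME_COLS = [
    "frame_id",
    "detected",
    "target_h",
    "target_v",
    "target_x",
    "target_y",
    "target_z",
    "eyeball_lx",
    "eyeball_ly",
    "eyeball_lz",
    "eyeball_rx",
    "eyeball_ry",
    "eyeball_rz",
    "eh_l",
    "ev_l",
    "eh_r",
    "ev_r",
    "hp",
    "hy",
    "hr",
]


def write_session(session: GazeSession, directory: str | Path) -> None:
    """Write a session as ``frames.csv`` + ``meta.json`` in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in session.frames:
        t2 = f.target_screen or (np.nan, np.nan)
        t3 = f.target_3d or (np.nan, np.nan, np.nan)
        bl = f.eyeball_left or (np.nan, np.nan, np.nan)
        br = f.eyeball_right or (np.nan, np.nan, np.nan)
        el = (f.eye_left.eh, f.eye_left.ev) if f.eye_left else (np.nan, np.nan)
        er = (f.eye_right.eh, f.eye_right.ev) if f.eye_right else (np.nan, np.nan)
        h = (f.head.pitch, f.head.yaw, f.head.roll) if f.head else (np.nan, np.nan, np.nan)
        rows.append([f.frame_id, int(f.detected), *t2, *t3, *bl, *br, *el, *er, *h])
    pd.DataFrame(rows, columns=_FRAME_COLS).to_csv(directory / "frames.csv", index=False)
    meta = {
        "name": session.name,
        "geometry": None if session.geometry is None else session.geometry.to_dict(),
        "camera": None
        if session.camera is None
        else {"f": session.camera.f, "cx": session.camera.cx, "cy": session.camera.cy},
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def read_session(directory: str | Path) -> GazeSession:
    """Read a session written by :func:`write_session`."""
    directory = Path(directory)
    df = pd.read_csv(directory / "frames.csv", dtype={"frame_id": str})
    missing = [c for c in _FRAME_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"session frames.csv missing columns: {missing}")
    meta = json.loads((directory / "meta.json").read_text())
    frames = []
    for _, r in df.iterrows():
        def _tup(*cols):
            vals = [r[c] for c in cols]
            return None if any(pd.isna(v) for v in vals) else tuple(float(v) for v in vals)

        el = _tup("eh_l", "ev_l")
        er = _tup("eh_r", "ev_r")
        h = _tup("hp", "hy", "hr")
        frames.append(
            GazeFrame(
                frame_id=str(r["frame_id"]),
                detected=bool(r["detected"]),
                target_screen=_tup("target_h", "target_v"),
                target_3d=_tup("target_x", "target_y", "target_z"),
                eyeball_left=_tup("eyeball_lx", "eyeball_ly", "eyeball_lz"),
                eyeball_right=_tup("eyeball_rx", "eyeball_ry", "eyeball_rz"),
                eye_left=None if el is None else EyeVector(*el, side="left"),
                eye_right=None if er is None else EyeVector(*er, side="right"),
                head=None if h is None else HeadPose(*h),
            )
        )
    geometry = (
        None if meta.get("geometry") is None else ScreenGeometry.from_dict(meta["geometry"])
    )
    camera = (
        None
        if meta.get("camera") is None
        else CameraModel(meta["camera"]["f"], meta["camera"]["cx"], meta["camera"]["cy"])
    )
    return GazeSession(frames=frames, geometry=geometry, camera=camera, name=meta.get("name", "session"))
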