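"""Eye-ROI extraction and the stable-landmark anchor point.

The input to every operation here is a 68-point facial landmark set in the
standard numbering (jaw 1-17, brows 18-27, nose 28-36, eyes 37-48, mouth
49-68), with the coordinate origin in the top-left corner of the image.
Landmark indices in the public API are 1-based to match that scheme.

Eye ROIs are rectangular crops bounded by the twelve eye landmarks:

    left eye  (subject's left, image right):
        X_l = P43.x,  X_r = P46.x,
        Y_t = min(P44.y, P45.y) - 3,  Y_b = max(P47.y, P48.y) + 3
    right eye (subject's right, image left):
        X_l = P37.x,  X_r = P40.x,
        Y_t = min(P38.y, P39.y) - 3,  Y_b = max(P41.y, P42.y) + 3

The crop is converted to grayscale, magnified by an integer factor (default
2) and cleaned with a grayscale erosion using a 1-pixel-radius disk element
(the 3x3 cross) before iris localization.

The anchor point is the arithmetic mean of the stable landmark subset --
by default indices 1-36 (all landmarks minus the 12 eye and 20 mouth
points, which vibrate with eye rotation and articulation), so n = 36.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .errors import ExtractionError, ValidationError

__all__ = [
    "LandmarkSet",
    "EyeROI",
    "AnchorPoint",
    "STABLE_LANDMARKS",
    "extract_eye_roi",
    "roi_to_image_coords",
    "image_to_roi_coords",
    "compute_anchor",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

N_LANDMARKS = 68

#: Default stable subset: jaw (1-17), brows (18-27), nose (28-36).
STABLE_LANDMARKS: tuple[int, ...] = tuple(range(1, 37))

#: BT.601 luma weights for color -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

#: 1-pixel-radius disk structuring element (3x3 cross).
_DISK1 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

_EYE_BOX_LANDMARKS = {
    # side -> (X_l idx, X_r idx, top idx pair, bottom idx pair)
    "left": (43, 46, (44, 45), (47, 48)),
    "right": (37, 40, (38, 39), (41, 42)),
}

_Y_MARGIN = 3.0  # px, applied in original-image pixels before magnification


@dataclass(frozen=True)
class LandmarkSet:
    """68 named 2D image points, origin top-left, 1-based indexing."""

    coords: np.ndarray  # (68, 2) float, columns x, y

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"expected {N_LANDMARKS} landmarks with (x, y), got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("landmark coordinates must be finite")
        if np.any(coords < 0):
            raise ValidationError("landmark coordinates must be non-negative")
        object.__setattr__(self, "coords", coords)

    def point(self, index: int) -> np.ndarray:
        """Return landmark ``index`` (1-based) as an (x, y) array."""
        if not 1 <= index <= N_LANDMARKS:
            raise ValidationError(f"landmark index {index} outside 1..{N_LANDMARKS}")
        return self.coords[index - 1]

    def __getitem__(self, index: int) -> np.ndarray:
        return self.point(index)

    def subset(self, indices: Iterable[int]) -> np.ndarray:
        """Coordinates of the given 1-based indices, shape (k, 2)."""
        idx = np.asarray(list(indices), dtype=int)
        if idx.size and (idx.min() < 1 or idx.max() > N_LANDMARKS):
            raise ValidationError("landmark indices outside 1..68")
        return self.coords[idx - 1]

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        return LandmarkSet(self.coords + np.array([dx, dy]))


@dataclass(frozen=True)
class EyeROI:
    """A cropped, magnified and eroded eye sub-image.

    ``origin`` is the top-left corner of the crop in full-image pixels;
    ``scale`` is the integer magnification; ``N`` and ``M`` are the
    post-magnification width and height. A point ``p`` in ROI coordinates
    maps back to the full image as ``origin + p / scale``.
    """

    image: np.ndarray  # (M, N) float grayscale
    side: str
    origin: tuple[float, float]
    scale: int = 2

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2 or img.size == 0:
            raise ValidationError("EyeROI image must be a non-empty 2D array")
        if self.scale < 1:
            raise ValidationError("EyeROI scale must be >= 1")
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")
        object.__setattr__(self, "image", img)

    @property
    def N(self) -> int:
        """Width in post-magnification pixels."""
        return self.image.shape[1]

    @property
    def M(self) -> int:
        """Height in post-magnification pixels."""
        return self.image.shape[0]


@dataclass(frozen=True)
class AnchorPoint:
    """Mean of a stable facial-landmark subset, full-image coordinates."""

    x: float
    y: float
    n: int = len(STABLE_LANDMARKS)

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image array to float grayscale (BT.601 luma for color)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[..., :3] @ _LUMA
    raise ValidationError(f"cannot interpret image of shape {img.shape}")


def eye_roi_box(landmarks: LandmarkSet, side: str) -> tuple[float, float, float, float]:
    """Boundary coordinates (X_l, X_r, Y_t, Y_b) of an eye ROI, full-image px."""
    try:
        xl_i, xr_i, top, bottom = _EYE_BOX_LANDMARKS[side]
    except KeyError:
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}") from None
    x_l = landmarks.point(xl_i)[0]
    x_r = landmarks.point(xr_i)[0]
    y_t = min(landmarks.point(top[0])[1], landmarks.point(top[1])[1]) - _Y_MARGIN
    y_b = max(landmarks.point(bottom[0])[1], landmarks.point(bottom[1])[1]) + _Y_MARGIN
    return x_l, x_r, y_t, y_b


def extract_eye_roi(
    image: np.ndarray,
    landmarks: LandmarkSet,
    side: str,
    *,
    scale: int = 2,
    interp_order: int = 1,
) -> EyeROI:
    """Extract, magnify and erode an eye ROI.

    Parameters
    ----------
    image : ndarray
        Full grayscale or color image.
    landmarks : LandmarkSet
        The 68-point landmark set for this image.
    side : {"left", "right"}
        Subject's left or right eye.
    scale : int
        Integer magnification factor (default 2).
    interp_order : int
        Interpolation order for the magnification: 0 nearest, 1 bilinear
        (default), 3 bicubic.
    """
    gray = to_grayscale(image)
    h, w = gray.shape
    x_l, x_r, y_t, y_b = eye_roi_box(landmarks, side)
    if x_r <= x_l or y_b <= y_t:
        raise ExtractionError(
            f"degenerate {side} eye box: x [{x_l}, {x_r}], y [{y_t}, {y_b}]"
        )
    xl = int(np.floor(x_l))
    xr = int(np.ceil(x_r))
    yt = int(np.floor(y_t))
    yb = int(np.ceil(y_b))
    cxl, cxr = max(xl, 0), min(xr, w - 1)
    cyt, cyb = max(yt, 0), min(yb, h - 1)
    if (cxl, cxr, cyt, cyb) != (xl, xr, yt, yb):
        warnings.warn(
            f"{side} eye box [{xl},{xr}]x[{yt},{yb}] exceeds image {w}x{h}; clipped",
            stacklevel=2,
        )
    crop = gray[cyt : cyb + 1, cxl : cxr + 1]
    if crop.shape[0] < 2 or crop.shape[1] < 2:
        raise ExtractionError(f"clipped {side} eye box is degenerate: {crop.shape}")
    magnified = resize(
        crop,
        (crop.shape[0] * scale, crop.shape[1] * scale),
        order=interp_order,
        preserve_range=True,
        anti_aliasing=False,
    )
    eroded = ndimage.grey_erosion(magnified, footprint=_DISK1)
    return EyeROI(image=eroded, side=side, origin=(float(cxl), float(cyt)), scale=scale)


def roi_to_image_coords(roi: EyeROI, p_roi: Sequence[float]) -> tuple[float, float]:
    """Map a point from ROI (post-magnification) to full-image coordinates."""
    x, y = float(p_roi[0]), float(p_roi[1])
    return roi.origin[0] + x / roi.scale, roi.origin[1] + y / roi.scale


def image_to_roi_coords(roi: EyeROI, p_image: Sequence[float]) -> tuple[float, float]:
    """Inverse of :func:`roi_to_image_coords`."""
    x, y = float(p_image[0]), float(p_image[1])
    return (x - roi.origin[0]) * roi.scale, (y - roi.origin[1]) * roi.scale


def compute_anchor(
    landmarks: LandmarkSet, indices: Sequence[int] | None = None
) -> AnchorPoint:
    """Anchor point: the mean of the stable landmark subset (default 1-36)."""
    if indices is None:
        indices = STABLE_LANDMARKS
    pts = landmarks.subset(indices)
    if pts.shape[0] < 3:
        raise ValidationError(
            f"need at least 3 stable landmarks for the anchor, got {pts.shape[0]}"
        )
    mean = pts.mean(axis=0)
    return AnchorPoint(x=float(mean[0]), y=float(mean[1]), n=pts.shape[0])


# ---------------------------------------------------------------------------
# Landmark CSV I/O: frame_id, x1, y1, ..., x68, y68 (header required)
# ---------------------------------------------------------------------------

def _landmark_columns() -> list[str]:
    cols = []
    for i in range(1, N_LANDMARKS + 1):
        cols += [f"x{i}", f"y{i}"]
    return cols


def write_landmarks_csv(path: str | Path, frames: dict[str, LandmarkSet]) -> None:
    """Write per-frame landmark rows to CSV."""
    cols = _landmark_columns()
    rows = []
    for frame_id, lm in frames.items():
        rows.append([frame_id] + list(lm.coords.ravel()))
    pd.DataFrame(rows, columns=["frame_id"] + cols).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> dict[str, LandmarkSet]:
    """Read per-frame landmark rows; returns {frame_id: LandmarkSet}."""
    df = pd.read_csv(path, dtype={"frame_id": str})
    cols = _landmark_columns()
    missing = [c for c in ["frame_id"] + cols if c not in df.columns]
    if missing:
        raise ValidationError(f"landmark CSV missing columns: {missing[:5]}...")
    out: dict[str, LandmarkSet] = {}
    for _, row in df.iterrows():
        coords = row[cols].to_numpy(dtype=float).reshape(N_LANDMARKS, 2)
        out[str(row["frame_id"])] = LandmarkSet(coords)
    return out
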