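"""Polynomial gaze mapping: eye vectors, mapping presets, fitting, fusion.

The eye vector is the 2D displacement from the anchor point to the iris
center in full-image pixels, e = (e_h, e_v). One mapping function predicts
one screen axis as a linear combination of monomials over
(e_h, e_v, h_p, h_y, h_r), where h_* are the head-pose angles in degrees:

    g = sum_k c_k * t_k(e_h, e_v, h_p, h_y, h_r)

Six nested presets are provided. No.1 and No.2 use linear and squared eye
terms only; No.3-No.6 mix in linear and squared head-pose terms:

    No.1  {1, e_h, e_v}
    No.2  {1, e_h, e_v, e_h*e_v, e_h^2, e_v^2}
    No.3  No.1 + {h_p, h_y, h_r}
    No.4  No.2 + {h_p, h_y, h_r}
    No.5  No.3 + {h_p^2, h_y^2, h_r^2}
    No.6  No.4 + {h_p^2, h_y^2, h_r^2}

Coefficients are fitted by ordinary least squares during calibration. The
best-performing defaults are preset No.4 for the horizontal axis and No.2
for the vertical axis. Left and right eyes get independent models; the
fused point of regard is the convex combination

    g_f = w * g_left + (1 - w) * g_right,   0 <= w <= 1,

with w = 0.5 by default (w = 1 is pure left, w = 0 pure right; when one
eye is unavailable w collapses to the other).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FitError, ValidationError
from .face_features import AnchorPoint
from .headpose import HeadPose

__all__ = [
    "EyeVector",
    "MappingModel",
    "PRESETS",
    "TERM_EXPONENTS",
    "DEFAULT_PRESET_H",
    "DEFAULT_PRESET_V",
    "eye_vector",
    "design_row",
    "design_matrix",
    "fit_mapping",
    "predict_por",
    "fuse_por",
]

logger = logging.getLogger(__name__)

#: Term name -> exponents (i, j, a, b, c) of e_h^i e_v^j h_p^a h_y^b h_r^c.
TERM_EXPONENTS: dict[str, tuple[int, int, int, int, int]] = {
    "1": (0, 0, 0, 0, 0),
    "eh": (1, 0, 0, 0, 0),
    "ev": (0, 1, 0, 0, 0),
    "eh*ev": (1, 1, 0, 0, 0),
    "eh^2": (2, 0, 0, 0, 0),
    "ev^2": (0, 2, 0, 0, 0),
    "hp": (0, 0, 1, 0, 0),
    "hy": (0, 0, 0, 1, 0),
    "hr": (0, 0, 0, 0, 1),
    "hp^2": (0, 0, 2, 0, 0),
    "hy^2": (0, 0, 0, 2, 0),
    "hr^2": (0, 0, 0, 0, 2),
}

_P1 = ("1", "eh", "ev")
_P2 = ("1", "eh", "ev", "eh*ev", "eh^2", "ev^2")
_HEAD_LIN = ("hp", "hy", "hr")
_HEAD_SQ = ("hp^2", "hy^2", "hr^2")

#: The six mapping-function presets (nested term sets).
PRESETS: dict[int, tuple[str, ...]] = {
    1: _P1,
    2: _P2,
    3: _P1 + _HEAD_LIN,
    4: _P2 + _HEAD_LIN,
    5: _P1 + _HEAD_LIN + _HEAD_SQ,
    6: _P2 + _HEAD_LIN + _HEAD_SQ,
}

DEFAULT_PRESET_H = 4
DEFAULT_PRESET_V = 2


@dataclass(frozen=True)
class EyeVector:
    """Iris center minus anchor point, full-image pixels."""

    eh: float
    ev: float
    side: str = "left"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eh) and np.isfinite(self.ev)):
            raise ValidationError("eye vector components must be finite")


def eye_vector(iris_center, anchor: AnchorPoint, side: str = "left") -> EyeVector:
    """e = iris center - anchor point, both in full-image coordinates.

    ``iris_center`` may be an (x, y) pair or an :class:`~gazekit.iris.IrisResult`
    (its full-image center is used; a result without one indicates the ROI
    lost its mapping back to the image and is a contract violation).
    """
    center_image = getattr(iris_center, "center_image", iris_center)
    if center_image is None:
        raise ValidationError(
            "iris result carries no full-image center; eye vectors must be "
            "computed in full-image coordinates, not ROI coordinates"
        )
    x, y = float(center_image[0]), float(center_image[1])
    return EyeVector(eh=x - anchor.x, ev=y - anchor.y, side=side)


def _resolve_terms(preset: int | Sequence[str]) -> tuple[str, ...]:
    if isinstance(preset, int):
        try:
            return PRESETS[preset]
        except KeyError:
            raise ValidationError(f"unknown mapping preset {preset}; valid: 1..6") from None
    terms = tuple(preset)
    unknown = [t for t in terms if t not in TERM_EXPONENTS]
    if unknown:
        raise ValidationError(f"unknown mapping terms {unknown}")
    if "1" not in terms:
        raise ValidationError("the constant term '1' must be included")
    return terms


def design_row(
    e: EyeVector, h: HeadPose | None, preset: int | Sequence[str]
) -> np.ndarray:
    """Monomial values of one frame for the given preset/term list."""
    terms = _resolve_terms(preset)
    hp, hy, hr = (0.0, 0.0, 0.0) if h is None else (h.pitch, h.yaw, h.roll)
    row = np.empty(len(terms))
    for k, t in enumerate(terms):
        i, j, a, b, c = TERM_EXPONENTS[t]
        row[k] = (e.eh**i) * (e.ev**j) * (hp**a) * (hy**b) * (hr**c)
    return row


def design_matrix(
    frames: Sequence[tuple[EyeVector, HeadPose | None]], preset: int | Sequence[str]
) -> np.ndarray:
    """Stack of design rows, shape (n_frames, n_terms)."""
    return np.array([design_row(e, h, preset) for e, h in frames])


@dataclass
class MappingModel:
    """One fitted mapping function for one screen axis.

    ``terms`` is the explicit monomial list; ``preset`` records the preset
    id when the terms came from one. ``coefficients`` is None until fitted.
    """

    axis: str  # "h" or "v"
    terms: tuple[str, ...]
    preset: int | None = None
    coefficients: np.ndarray | None = None
    residual_rms: float | None = None
    condition_number: float | None = None

    def __post_init__(self) -> None:
        if self.axis not in ("h", "v"):
            raise ValidationError("axis must be 'h' or 'v'")
        self.terms = _resolve_terms(self.terms)
        if self.coefficients is not None:
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if self.coefficients.shape != (len(self.terms),):
                raise ValidationError(
                    f"{len(self.terms)} terms but "
                    f"{self.coefficients.shape} coefficients"
                )

    @classmethod
    def from_preset(cls, preset: int, axis: str) -> "MappingModel":
        return cls(axis=axis, terms=_resolve_terms(preset), preset=preset)

    def predict(self, e: EyeVector, h: HeadPose | None = None) -> float:
        if self.coefficients is None:
            raise FitError("mapping model has not been fitted")
        return float(self.coefficients @ design_row(e, h, self.terms))

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "preset": self.preset,
            "terms": list(self.terms),
            "coefficients": None
            if self.coefficients is None
            else self.coefficients.tolist(),
            "diagnostics": {
                "residual_rms": self.residual_rms,
                "condition_number": self.condition_number,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MappingModel":
        m = cls(
            axis=d["axis"],
            terms=tuple(d["terms"]),
            preset=d.get("preset"),
            coefficients=None
            if d.get("coefficients") is None
            else np.array(d["coefficients"], dtype=float),
        )
        diag = d.get("diagnostics") or {}
        m.residual_rms = diag.get("residual_rms")
        m.condition_number = diag.get("condition_number")
        return m

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MappingModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_mapping(
    frames: Sequence[tuple[EyeVector, HeadPose | None]],
    targets: Sequence[float],
    preset: int | Sequence[str],
    axis: str,
) -> MappingModel:
    """Ordinary least-squares fit of one mapping function.

    Requires at least as many frames as terms and a full-rank design
    matrix; a rank-deficiency error names the suspect (collinear) terms.
    """
    terms = _resolve_terms(preset)
    y = np.asarray(targets, dtype=float)
    if len(frames) != y.shape[0]:
        raise ValidationError(f"{len(frames)} frames but {y.shape[0]} targets")
    if len(frames) < len(terms):
        raise FitError(
            f"need at least {len(terms)} frames to fit {len(terms)} terms, "
            f"got {len(frames)}"
        )
    X = design_matrix(frames, terms)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * s[0]
    rank = int((s > tol).sum())
    if rank < len(terms):
        null_mask = np.abs(Vt[rank:]).max(axis=0) > 1e-3
        suspects = [t for t, bad in zip(terms, null_mask) if bad]
        raise FitError(
            f"design matrix rank {rank} < {len(terms)} terms; "
            f"collinear terms: {suspects} (e.g. all frames at one gaze point)"
        )
    coeffs = Vt.T @ ((U.T @ y) / s)
    resid = X @ coeffs - y
    model = MappingModel(
        axis=axis,
        terms=terms,
        preset=preset if isinstance(preset, int) else None,
        coefficients=coeffs,
    )
    model.residual_rms = float(np.sqrt(np.mean(resid**2)))
    model.condition_number = float(s[0] / s[-1])
    return model


def predict_por(
    model_h: MappingModel,
    model_v: MappingModel,
    e: EyeVector,
    h: HeadPose | None = None,
) -> tuple[float, float]:
    """Point of regard (g_h, g_v) from the two per-axis mapping functions."""
    return model_h.predict(e, h), model_v.predict(e, h)


def fuse_por(
    left: tuple[float, float],
    right: tuple[float, float],
    w: float = 0.5,
    w_v: float | None = None,
    left_available: bool = True,
    right_available: bool = True,
) -> tuple[float, float]:
    """Weighted binocular fusion: g_f = w * left + (1 - w) * right.

    ``w_v`` optionally weights the vertical axis differently. If one eye is
    flagged unavailable its weight collapses to 0 (logged).
    """
    if not 0 <= w <= 1:
        raise ValidationError(f"w must lie in [0, 1], got {w}")
    wv = w if w_v is None else w_v
    if not 0 <= wv <= 1:
        raise ValidationError(f"w_v must lie in [0, 1], got {wv}")
    if not left_available and not right_available:
        raise ValidationError("at least one eye must be available")
    if not left_available:
        logger.info("left eye unavailable; w collapsed to 0 (right eye only)")
        w, wv = 0.0, 0.0
    elif not right_available:
        logger.info("right eye unavailable; w collapsed to 1 (left eye only)")
        w, wv = 1.0, 1.0
    g_fh = w * left[0] + (1.0 - w) * right[0]
    g_fv = wv * left[1] + (1.0 - wv) * right[1]
    return g_fh, g_fv
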