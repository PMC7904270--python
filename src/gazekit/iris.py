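"""Iris-center localization with an anatomically initialized snakuscule.

A snakuscule is a minimal circular active contour: an inner disk of radius
``r`` and an outer annulus extending to ``beta * r``. On an eye ROI the iris
is a dark disk on a lighter sclera, so the probe is scored by the gray-level
contrast

    G(p) = mean f over the annulus  -  mean f over the disk,

with pixel membership decided by the Euclidean distance from the pixel
center to the probe center. Instead of evolving the contour iteratively,
the inner radius is fixed from anatomy -- the iris radius is close to a
constant (~7 mm) and the eye-ROI width is close to the eyeball diameter
(~25 mm) -- as ``r = round(alpha * N)`` with ``alpha ~ 0.25``, and the
probe is

1. scanned left to right along the horizontal centerline ``y = floor(M/2)``
   at integer ``x`` (the argmax is the rough center ``p_rc``), then
2. evaluated on the ``(2*delta+1) x (2*delta+1)`` integer grid of candidate
   points around ``p_rc``; the argmax is the final iris center ``p_c``.

Default parameters ``alpha=0.25, beta=1.4, delta=2`` are the sweep optimum
on the GI4E benchmark. All tie-breaks are deterministic: the rough scan
keeps the smallest x; refinement keeps the candidate nearest to ``p_rc``,
then the first in row-major order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import BoundaryError, ValidationError
from .face_features import EyeROI, roi_to_image_coords

__all__ = [
    "Snakuscule",
    "IrisResult",
    "init_radius",
    "energy",
    "scan_rough",
    "refine",
    "locate_iris",
]


@dataclass(frozen=True)
class Snakuscule:
    """Circular two-region probe: inner disk radius ``r``, outer ``beta*r``."""

    x: int
    y: int
    r: int
    beta: float = 1.4

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValidationError(f"inner radius must be >= 1, got {self.r}")
        if self.beta <= 1:
            raise ValidationError(f"beta must exceed 1, got {self.beta}")

    @property
    def outer_radius(self) -> float:
        return self.beta * self.r


@dataclass(frozen=True)
class IrisResult:
    """Rough and refined iris centers with their energies and parameters."""

    rough_center: tuple[int, int]       # ROI coordinates
    final_center: tuple[int, int]       # ROI coordinates
    energy_rough: float
    energy_final: float
    center_image: tuple[float, float] | None  # full-image coordinates
    alpha: float
    beta: float
    delta: int
    r: int


def init_radius(N: int, alpha: float = 0.25) -> int:
    """Inner radius from the eye-anatomy prior: r = round(alpha * N), >= 1.

    ``alpha`` is the ratio of iris radius to eye-ROI width; the ROI width
    tracks the eyeball diameter, and iris radius / eyeball diameter is
    roughly 7 / 25 ~ 0.28, so alpha near 0.25 is anatomically grounded.
    Rounding is half-up so the radius is stable across platforms.
    """
    if N < 8:
        raise ValidationError(f"ROI width N={N} too small (need >= 8)")
    if not 0 < alpha < 0.5:
        raise ValidationError(f"alpha must lie in (0, 0.5), got {alpha}")
    return max(1, int(math.floor(alpha * N + 0.5)))


@lru_cache(maxsize=64)
def _region_offsets(r: int, beta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Integer (dy, dx) offsets of the disk and annulus, by center distance."""
    R = int(math.floor(beta * r))
    dy, dx = np.mgrid[-R : R + 1, -R : R + 1]
    d2 = dx * dx + dy * dy
    disk = d2 <= r * r
    annulus = (d2 > r * r) & (d2 <= (beta * r) ** 2)
    return dy[disk], dx[disk], dy[annulus], dx[annulus]


def energy(image: np.ndarray, s: Snakuscule) -> float:
    """Gray-difference energy G = mean(annulus) - mean(disk).

    Raises :class:`BoundaryError` if any probe pixel falls outside the
    image; callers must restrict the scan range accordingly.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("energy expects a 2D grayscale image")
    M, N = img.shape
    R = int(math.floor(s.beta * s.r))
    if s.x - R < 0 or s.x + R > N - 1 or s.y - R < 0 or s.y + R > M - 1:
        raise BoundaryError(
            f"snakuscule at ({s.x},{s.y}) with outer radius {s.outer_radius:.1f} "
            f"extends outside the {N}x{M} image"
        )
    dy_d, dx_d, dy_a, dx_a = _region_offsets(s.r, s.beta)
    disk_mean = img[s.y + dy_d, s.x + dx_d].mean()
    annulus_mean = img[s.y + dy_a, s.x + dx_a].mean()
    return float(annulus_mean - disk_mean)


def _scan_positions(N: int, r: int, beta: float) -> range:
    """Integer x positions of the centerline scan, probe kept inside."""
    R = int(math.floor(beta * r))
    lo = max(int(math.ceil(beta * r)), R)
    hi = min(int(math.floor(N - beta * r)), N - 1 - R)
    return range(lo, hi + 1)


def scan_rough(roi: EyeROI | np.ndarray, r: int, beta: float = 1.4) -> tuple[int, int]:
    """Rough iris center: argmax of G along the horizontal centerline.

    Evaluates the probe at integer ``x`` in ``[ceil(beta*r), floor(N-beta*r)]``
    (intersected with positions where the probe lies wholly inside) at
    ``y = floor(M/2)``. Ties keep the smallest x.
    """
    img = roi.image if isinstance(roi, EyeROI) else np.asarray(roi, dtype=float)
    M, N = img.shape
    y = M // 2
    xs = _scan_positions(N, r, beta)
    R = int(math.floor(beta * r))
    if len(xs) == 0 or y - R < 0 or y + R > M - 1:
        raise BoundaryError(
            f"no valid scan positions in a {N}x{M} ROI with r={r}, beta={beta}; "
            "use a larger ROI or a smaller beta"
        )
    best_x, best_g = None, -np.inf
    for x in xs:
        g = energy(img, Snakuscule(x, y, r, beta))
        if g > best_g:  # strict: ties keep the smallest x
            best_x, best_g = x, g
    return int(best_x), int(y)


def refine(
    roi: EyeROI | np.ndarray,
    p_rc: tuple[int, int],
    r: int,
    beta: float = 1.4,
    delta: int = 2,
) -> tuple[int, int]:
    """Final iris center: argmax of G over the (2*delta+1)^2 candidate grid.

    Candidates outside the valid probe area are clipped away. Ties keep the
    candidate nearest to ``p_rc`` (Euclidean), then row-major order.
    """
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    img = roi.image if isinstance(roi, EyeROI) else np.asarray(roi, dtype=float)
    M, N = img.shape
    R = int(math.floor(beta * r))
    x0, y0 = int(p_rc[0]), int(p_rc[1])
    best = None  # (-g, dist2, row-major index)
    best_pos = None
    idx = 0
    for y in range(y0 - delta, y0 + delta + 1):
        for x in range(x0 - delta, x0 + delta + 1):
            idx += 1
            if x - R < 0 or x + R > N - 1 or y - R < 0 or y + R > M - 1:
                continue  # clipped to valid probe area
            g = energy(img, Snakuscule(x, y, r, beta))
            d2 = (x - x0) ** 2 + (y - y0) ** 2
            key = (-g, d2, idx)
            if best is None or key < best:
                best = key
                best_pos = (x, y)
    if best_pos is None:
        raise BoundaryError("no refinement candidate keeps the probe inside the ROI")
    return best_pos


def locate_iris(
    roi: EyeROI,
    alpha: float = 0.25,
    beta: float = 1.4,
    delta: int = 2,
) -> IrisResult:
    """Full localization: init_radius -> scan_rough -> refine.

    The final center is reported both in ROI coordinates and, through the
    ROI's origin/scale, in full-image coordinates.
    """
    r = init_radius(roi.N, alpha)
    p_rc = scan_rough(roi, r, beta)
    g_rough = energy(roi.image, Snakuscule(p_rc[0], p_rc[1], r, beta))
    p_c = refine(roi, p_rc, r, beta, delta)
    g_final = energy(roi.image, Snakuscule(p_c[0], p_c[1], r, beta))
    return IrisResult(
        rough_center=p_rc,
        final_center=p_c,
        energy_rough=g_rough,
        energy_final=g_final,
        center_image=roi_to_image_coords(roi, p_c),
        alpha=alpha,
        beta=beta,
        delta=delta,
        r=r,
    )
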