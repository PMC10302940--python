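"""Point-set pyramid matching and NCC template tracking for camera verification.

Two matching engines:

* **Histogram pyramid** — a point set in a square domain of side D (a power of
  two, padded up if not) is binned at L = log2(D) + 1 resolutions; level i uses
  axis-aligned bins of side 2^i, so level i holds (D / 2^i)^d addressable bins.
  Two pyramids are compared by min-intersection: matches newly formed at level
  i (coarser bins) are weighted 1/2^i, approximating the optimal point
  assignment without computing pairwise distances.

* **Normalized cross-correlation (NCC)** — template localisation in gray
  images, bounded in [-1, 1] and invariant to positive affine intensity
  changes of the template.  Three distinctly shaped marker templates are
  tracked per frame and converted to shoulder-origin cm coordinates through a
  scalar pixel calibration.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.feature import match_template

from .errors import ConstantTemplateError, InputError

__all__ = [
    "PointSet2D",
    "HistogramPyramid",
    "Template",
    "TrackedMarkers",
    "build_pyramid",
    "pyramid_match_score",
    "ncc_match",
    "track_markers",
    "render_frame",
    "marker_templates",
]


def _next_power_of_two(x: float) -> int:
    return 1 << max(0, math.ceil(math.log2(max(x, 1.0))))


@dataclass(frozen=True)
class PointSet2D:
    """Points in [0, D)^d with D a power of two (padded up at construction)."""

    points: np.ndarray
    D: int
    d: int = 2

    @classmethod
    def create(cls, points, D: Optional[int] = None) -> "PointSet2D":
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        if len(pts) and np.min(pts) < 0:
            raise InputError("all coordinates must be >= 0")
        needed = float(np.max(pts)) + 1.0 if len(pts) else 1.0
        side = D if D is not None else needed
        if side < 1:
            raise InputError("domain side must be >= 1")
        side = _next_power_of_two(side)
        if len(pts) and np.max(pts) >= side:
            raise InputError(f"points must lie in [0, {side})")
        return cls(points=pts, D=side)


@dataclass(frozen=True)
class HistogramPyramid:
    """Sparse multi-resolution histograms H_0 .. H_{L-1} of one point set.

    levels[i] maps an integer bin address (tuple) to its occupancy; bins at
    level i have side 2^i, so every level conserves the total point count.
    """

    levels: tuple
    L: int
    D: int
    d: int
    n_points: int


@dataclass(frozen=True)
class Template:
    """Gray-value template for NCC matching; must have nonzero variance."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InputError("template must be a 2-D gray grid")
        if np.var(v) == 0:
            raise ConstantTemplateError("constant template: NCC undefined")


def build_pyramid(X: PointSet2D) -> HistogramPyramid:
    """Bin the point set at every resolution level of the pyramid."""
    L = int(math.log2(X.D)) + 1
    levels = []
    for i in range(L):
        side = 2**i
        if len(X.points):
            bins = np.floor(X.points / side).astype(int)
            levels.append(Counter(map(tuple, bins)))
        else:
            levels.append(Counter())
    return HistogramPyramid(levels=tuple(levels), L=L, D=X.D, d=X.d, n_points=len(X.points))


def pyramid_match_score(px: HistogramPyramid, py: HistogramPyramid) -> float:
    """Weighted count of newly matched points across pyramid levels.

    score = sum_i N_i / 2^i where N_i = I_i - I_{i-1} and
    I_i = sum_b min(H_i^X[b], H_i^Y[b]).  Symmetric; score(X, X) = |X|.
    """
    if px.D != py.D or px.d != py.d:
        raise InputError("pyramids built on different domains cannot be matched")
    score = 0.0
    prev = 0
    for i in range(px.L):
        hx, hy = px.levels[i], py.levels[i]
        if len(hy) < len(hx):
            hx, hy = hy, hx
        inter = sum(min(c, hy[b]) for b, c in hx.items())
        score += (inter - prev) / 2.0**i
        prev = inter
    return score


def ncc_match(image: np.ndarray, template: Template) -> tuple[tuple[int, int], np.ndarray]:
    """Locate a template in a gray image by normalized cross-correlation.

    Returns the (row, col) of the best top-left offset and the full
    correlation map (values in [-1, 1]).
    """
    img = np.asarray(image, dtype=float)
    tpl = np.asarray(template.values, dtype=float)
    if img.ndim != 2:
        raise InputError("image must be a 2-D gray grid")
    if tpl.shape[0] > img.shape[0] or tpl.shape[1] > img.shape[1]:
        raise InputError("template larger than image")
    corr = match_template(img, tpl)
    corr = np.clip(corr, -1.0, 1.0)
    best = np.unravel_index(int(np.argmax(corr)), corr.shape)
    return (int(best[0]), int(best[1])), corr


@dataclass(frozen=True)
class TrackedMarkers:
    """Per-frame marker positions in cm, re-based to the shoulder track.

    positions_cm has shape (n_frames, n_markers, 2) in (x, y) order; lost
    detections (peak correlation below the floor) are NaN with valid=False.
    """

    positions_cm: np.ndarray
    peak_corr: np.ndarray
    valid: np.ndarray
    cm_per_pixel: float


def track_markers(
    frames: Sequence[np.ndarray],
    templates: Sequence[Template],
    cm_per_pixel: float,
    min_correlation: float = 0.5,
) -> TrackedMarkers:
    """NCC-localise each template in each frame and convert to cm.

    Marker 0 is the shoulder and defines the coordinate origin; frames where a
    template's best correlation falls below ``min_correlation`` are flagged as
    gaps (NaN), never interpolated.
    """
    if len(frames) < 1:
        raise InputError("need at least one frame")
    if cm_per_pixel <= 0:
        raise InputError("cm_per_pixel must be positive")
    n_f, n_m = len(frames), len(templates)
    pos_px = np.full((n_f, n_m, 2), np.nan)
    peak = np.zeros((n_f, n_m))
    valid = np.zeros((n_f, n_m), dtype=bool)

    for fi, frame in enumerate(frames):
        for mi, tpl in enumerate(templates):
            (row, col), corr = ncc_match(frame, tpl)
            peak[fi, mi] = corr[row, col]
            if corr[row, col] >= min_correlation:
                h, w = np.asarray(tpl.values).shape
                # centre of the matched window, image (row, col) -> plane (x, y)
                pos_px[fi, mi] = (col + (w - 1) / 2.0, row + (h - 1) / 2.0)
                valid[fi, mi] = True

    pos_cm = pos_px * cm_per_pixel
    pos_cm = pos_cm - pos_cm[:, [0], :]  # shoulder-origin re-basing
    return TrackedMarkers(positions_cm=pos_cm, peak_corr=peak, valid=valid, cm_per_pixel=cm_per_pixel)


# ---------------------------------------------------------------------------
# synthetic rendering helpers (for round-trip verification)


def marker_templates(size: int = 9) -> list[Template]:
    """Three distinctly shaped gray markers: disc, cross, square outline."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    disc = ((yy - c) ** 2 + (xx - c) ** 2 <= (c * 0.9) ** 2).astype(float)
    cross = ((np.abs(yy - c) <= 1) | (np.abs(xx - c) <= 1)).astype(float)
    ring = np.zeros((size, size))
    ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = 1.0
    ring[1, :] = ring[-2, :] = ring[:, 1] = ring[:, -2] = 1.0
    return [Template(disc * 255.0), Template(cross * 255.0), Template(ring * 255.0)]


def render_frame(
    shape: tuple[int, int],
    centers_px: Sequence[tuple[float, float]],
    templates: Sequence[Template],
    noise_std: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Paste templates centred at (x, y) pixel positions into a blank frame."""
    frame = np.zeros(shape, dtype=float)
    for (x, y), tpl in zip(centers_px, templates):
        v = np.asarray(tpl.values, dtype=float)
        h, w = v.shape
        r0 = int(round(y - (h - 1) / 2.0))
        c0 = int(round(x - (w - 1) / 2.0))
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
            raise InputError("template placement outside the frame")
        frame[r0 : r0 + h, c0 : c0 + w] += v
    if noise_std > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        frame = frame + noise_std * 255.0 * rng.standard_normal(shape)
    return frame
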