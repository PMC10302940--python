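"""Geometric elbow recovery from a single wrist observation.

The reduced-IMU core: with the shoulder fixed at the origin, the elbow lies on
the circle C1 of radius l1 about the origin AND on the circle C2 of radius l2
about the measured wrist position (a, b):

    x^2 + y^2             = l1^2    (C1)
    (x - a)^2 + (y - b)^2 = l2^2    (C2)

Subtracting the two equations collapses the system to the radical line

    2 a x + 2 b y = a^2 + b^2 + l1^2 - l2^2,

which together with C1 yields at most two candidate elbow positions.  The
ambiguity is resolved with the wrist IMU's yaw: the forearm heading implied by
a candidate, atan2(wrist - candidate), must agree with the measured yaw.  When
no yaw is available the solver falls back to temporal continuity with the
previous elbow, and finally to the anatomical default of the upper candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InputError, ReachabilityError
from .synthgen import ArmGeometry

__all__ = [
    "PlanePoint",
    "WristObservation",
    "ElbowSolution",
    "circle_circle_intersect",
    "elbow_from_wrist",
    "track_elbow",
]

# relative tolerance (fraction of l1+l2) inside which an out-of-annulus wrist
# is clamped to the nearest feasible radius; absorbs the ~0.5 cm soft-tissue
# fluctuation of the upper-arm length
REACH_TOLERANCE = 0.01


@dataclass(frozen=True)
class PlanePoint:
    """A point in the shoulder-origin X-Y plane, cm."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"non-finite plane point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class WristObservation:
    """Measured wrist position (centre of circle C2) and IMU yaw, rad.

    yaw_alpha may be NaN when no heading is available.
    """

    position: PlanePoint
    yaw_alpha: float = math.nan


@dataclass(frozen=True)
class ElbowSolution:
    """Candidate elbow positions, the selected one and the rule that chose it.

    branch is one of 'unique', 'yaw', 'previous', 'upper'.  ``clamped`` marks
    observations that were radially clamped onto the reachable annulus.
    """

    candidates: tuple
    selected: Optional[PlanePoint]
    branch: str
    clamped: bool = False


def circle_circle_intersect(l1: float, center: PlanePoint, l2: float) -> list[PlanePoint]:
    """Intersect C1 (origin, radius l1) with C2 (center, radius l2).

    Returns 0, 1 or 2 points; tangency collapses the pair to one point.
    Raises DegenerateGeometryError for coincident circles.
    """
    if l1 <= 0 or l2 <= 0:
        raise InputError("circle radii must be positive")
    a, b = center.x, center.y
    d = math.hypot(a, b)
    if d < 1e-12:
        raise DegenerateGeometryError("concentric circles: intersection is empty or a full circle")

    # distance from the origin to the radical line along the centre line
    x0 = (d * d + l1 * l1 - l2 * l2) / (2.0 * d)
    h2 = l1 * l1 - x0 * x0
    tol = 1e-9 * max(1.0, l1 * l1)
    if h2 < -tol:
        return []
    ux, uy = a / d, b / d
    bx, by = x0 * ux, x0 * uy
    if h2 <= tol:
        return [PlanePoint(bx, by)]
    h = math.sqrt(h2)
    ox, oy = -uy * h, ux * h
    return [PlanePoint(bx + ox, by + oy), PlanePoint(bx - ox, by - oy)]


def _wrap_angle(x: float) -> float:
    return (x + math.pi) % (2.0 * math.pi) - math.pi


def elbow_from_wrist(
    obs: WristObservation,
    geom: ArmGeometry,
    previous: Optional[PlanePoint] = None,
    tolerance: float = REACH_TOLERANCE,
) -> ElbowSolution:
    """Solve the two-circle system for the elbow and disambiguate the branch.

    Selection order: forearm heading consistency with the measured yaw;
    minimal displacement from ``previous``; anatomical default (larger y).
    ``tolerance`` (fraction of l1+l2) bounds how far outside the reachable
    annulus a wrist may sit before it is rejected instead of clamped;
    ``math.inf`` clamps unconditionally (useful downstream of a drifting
    position estimator).
    """
    l1, l2 = geom.l1, geom.l2
    pos = obs.position
    r = math.hypot(pos.x, pos.y)
    r_min, r_max = abs(l1 - l2), l1 + l2
    tol = tolerance * (l1 + l2)

    clamped = False
    if r < r_min - tol or r > r_max + tol:
        raise ReachabilityError(
            f"wrist radius {r:.3f} cm outside reachable annulus [{r_min:.3f}, {r_max:.3f}]"
        )
    if r > r_max or (r < r_min and r_min > 0):
        if r < 1e-12:
            raise ReachabilityError("wrist at the shoulder origin; direction undefined")
        target = min(max(r, r_min), r_max)
        # shrink just inside the boundary so the intersection is numerically robust
        target = target * (1.0 - 1e-12) if target == r_max else target * (1.0 + 1e-12)
        scale = target / r
        pos = PlanePoint(pos.x * scale, pos.y * scale)
        clamped = True

    candidates = circle_circle_intersect(l1, pos, l2)
    if not candidates:
        raise ReachabilityError("no circle intersection despite feasible wrist radius")
    if len(candidates) == 1:
        return ElbowSolution(tuple(candidates), candidates[0], "unique", clamped)

    if math.isfinite(obs.yaw_alpha):
        def yaw_error(c: PlanePoint) -> float:
            heading = math.atan2(obs.position.y - c.y, obs.position.x - c.x)
            return abs(_wrap_angle(heading - obs.yaw_alpha))

        selected = min(candidates, key=yaw_error)
        return ElbowSolution(tuple(candidates), selected, "yaw", clamped)

    if previous is not None:
        selected = min(
            candidates,
            key=lambda c: (c.x - previous.x) ** 2 + (c.y - previous.y) ** 2,
        )
        return ElbowSolution(tuple(candidates), selected, "previous", clamped)

    selected = max(candidates, key=lambda c: c.y)
    return ElbowSolution(tuple(candidates), selected, "upper", clamped)


def track_elbow(
    wrist_series: Sequence[WristObservation],
    geom: ArmGeometry,
    tolerance: float = REACH_TOLERANCE,
) -> list[ElbowSolution]:
    """Apply elbow_from_wrist sequentially, threading the previous selection."""
    if len(wrist_series) == 0:
        raise InputError("empty wrist series")
    out: list[ElbowSolution] = []
    previous: Optional[PlanePoint] = None
    for obs in wrist_series:
        sol = elbow_from_wrist(obs, geom, previous=previous, tolerance=tolerance)
        out.append(sol)
        if sol.selected is not None:
            previous = sol.selected
    return out
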