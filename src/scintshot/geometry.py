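"""2-D geometric primitives: lines, intersections, minimum enclosing circle.

The minimum enclosing circle is the radiation-isocenter estimator: its center
over the star-line intersection points is the radiation isocenter and its
radius quantifies gantry beam-axis wobble.  The implementation is Welzl's
randomized incremental algorithm (expected O(n)), made deterministic by a
fixed internal shuffle seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .errors import BadInputError, GeometryError

__all__ = ["Line2D", "CircleResult", "intersect_lines", "min_enclosing_circle"]

_SHUFFLE_SEED = 0x5EED  # fixed: results must not depend on input order


@dataclass(frozen=True)
class Line2D:
    """An infinite 2-D line: a point on it plus a unit direction.

    The direction is canonicalized to the upper half-plane (``dy > 0``, tie
    broken toward ``+x``) so each geometric line has a single representation.
    Under the raster convention "upper half-plane" means y-component > 0
    with y growing downward; the canonical form is purely representational.
    """

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        dx, dy = self.direction
        norm = math.hypot(dx, dy)
        if not norm > 0 or not (math.isfinite(dx) and math.isfinite(dy)):
            raise GeometryError("line direction must be a finite nonzero vector")
        dx, dy = dx / norm, dy / norm
        if dy < 0 or (dy == 0 and dx < 0):
            dx, dy = -dx, -dy
        object.__setattr__(self, "direction", (dx, dy))
        object.__setattr__(self, "point", (float(self.point[0]), float(self.point[1])))

    @classmethod
    def through(cls, p: np.ndarray, q: np.ndarray) -> "Line2D":
        """Line through two distinct points."""
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        return cls(point=(p[0], p[1]), direction=(q[0] - p[0], q[1] - p[1]))

    @property
    def angle_deg(self) -> float:
        """Orientation in degrees, in [0, 180)."""
        dx, dy = self.direction
        return math.degrees(math.atan2(dy, dx)) % 180.0

    @property
    def normal(self) -> tuple[float, float]:
        dx, dy = self.direction
        return (-dy, dx)

    def distance_to(self, p: np.ndarray) -> float:
        """Unsigned perpendicular distance from a point."""
        nx, ny = self.normal
        px, py = self.point
        q = np.asarray(p, dtype=float)
        return abs((q[0] - px) * nx + (q[1] - py) * ny)

    def scaled(self, factor: float) -> "Line2D":
        """The same line with its anchor point scaled (px → mm conversion)."""
        return Line2D(point=(self.point[0] * factor, self.point[1] * factor),
                      direction=self.direction)


def angle_between_deg(a: Line2D, b: Line2D) -> float:
    """Acute angle between two line orientations, in [0, 90]."""
    d = abs(a.angle_deg - b.angle_deg) % 180.0
    return min(d, 180.0 - d)


def intersect_lines(a: Line2D, b: Line2D, angle_tol_deg: float = 0.1) -> np.ndarray:
    """Intersection point of two non-parallel lines.

    Solves the 2x2 linear system ``a.point + t a.dir = b.point + s b.dir``.
    Lines parallel within ``angle_tol_deg`` raise :class:`GeometryError`.
    """
    if angle_between_deg(a, b) < angle_tol_deg:
        raise GeometryError(
            f"lines are parallel within {angle_tol_deg} deg "
            f"({a.angle_deg:.4f} vs {b.angle_deg:.4f})"
        )
    adx, ady = a.direction
    bdx, bdy = b.direction
    mat = np.array([[adx, -bdx], [ady, -bdy]], dtype=float)
    rhs = np.array([b.point[0] - a.point[0], b.point[1] - a.point[1]])
    t, _ = np.linalg.solve(mat, rhs)
    return np.array([a.point[0] + t * adx, a.point[1] + t * ady])


@dataclass(frozen=True)
class CircleResult:
    """Minimum enclosing circle: ``center_mm`` is the radiation isocenter.

    ``support_points`` are the 1-3 input points lying on the circle that
    determine it; removing any of them would shrink the circle.
    """

    center_mm: tuple[float, float]
    radius_mm: float
    support_points: tuple[tuple[float, float], ...] = field(default=())

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float)

    def contains(self, p: np.ndarray, slack: float = 1e-9) -> bool:
        return float(np.hypot(*(np.asarray(p, float) - self.center))) <= self.radius_mm + slack

    def scaled(self, factor: float) -> "CircleResult":
        return CircleResult(
            center_mm=(self.center_mm[0] * factor, self.center_mm[1] * factor),
            radius_mm=self.radius_mm * factor,
            support_points=tuple((x * factor, y * factor) for x, y in self.support_points),
        )


# --- Welzl machinery -------------------------------------------------------

def _circle_two(p, q):
    cx = (p[0] + q[0]) / 2.0
    cy = (p[1] + q[1]) / 2.0
    r = math.hypot(p[0] - cx, p[1] - cy)
    return (cx, cy, r, (p, q))


def _circle_three(p, q, r):
    """Circumcircle; None when the triple is (near-)collinear."""
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14 * max(1.0, abs(ax), abs(ay), abs(bx), abs(by), abs(cx), abs(cy)) ** 2:
        return None
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    rad = math.hypot(ax - ux, ay - uy)
    return (ux, uy, rad, (p, q, r))


def _inside(circle, p, eps):
    cx, cy, r, _ = circle
    return math.hypot(p[0] - cx, p[1] - cy) <= r * (1.0 + eps) + eps


def min_enclosing_circle(points, eps: float = 1e-12) -> CircleResult:
    """Exact minimum enclosing circle of a 2-D point set.

    Welzl's move-to-front algorithm with a fixed internal shuffle seed, so
    the result (including the support set) is deterministic and independent
    of input order up to floating-point tie handling.

    Raises :class:`BadInputError` on empty input.
    """
    pts = [tuple(map(float, p)) for p in np.atleast_2d(np.asarray(points, dtype=float))] \
        if len(points) else []
    if not pts:
        raise BadInputError("min_enclosing_circle requires at least one point")
    rng = random.Random(_SHUFFLE_SEED)
    rng.shuffle(pts)

    c = (pts[0][0], pts[0][1], 0.0, (pts[0],))
    for i, p in enumerate(pts[1:], start=1):
        if _inside(c, p, eps):
            continue
        # smallest circle of pts[:i] with p on the boundary
        c = (p[0], p[1], 0.0, (p,))
        for j, q in enumerate(pts[:i]):
            if _inside(c, q, eps):
                continue
            # smallest circle with p and q on the boundary
            c = _circle_two(p, q)
            for r in pts[:j]:
                if _inside(c, r, eps):
                    continue
                c3 = _circle_three(p, q, r)
                if c3 is None:
                    # collinear triple: the widest diameter circle covers all
                    c3 = max((_circle_two(p, r), _circle_two(q, r), _circle_two(p, q)),
                             key=lambda cc: cc[2])
                c = c3
    cx, cy, rad, support = c
    return CircleResult(center_mm=(cx, cy), radius_mm=rad,
                        support_points=tuple(support))
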