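"""Bounded convex domains: interval, convex polygon, disk.

Domains are closed sets (boundary points count as inside); for
continuous step laws the boundary carries zero probability, so no
statistic depends on this choice, but it makes stop-go termination
points representable.
"""

from __future__ import annotations

import logging

import numpy as np
import shapely.affinity
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Interval",
    "ConvexPolygon",
    "Disk",
    "contains",
    "area",
    "diameter",
    "uniform_sample",
    "clip_intersection",
    "reflect_fold_1d",
]

logger = logging.getLogger(__name__)

_HALFPLANE_TOL = 1e-12  # slack in half-plane tests at shared edges


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class Interval:
    """Segment [0, L] on the line."""

    dim = 1

    def __init__(self, length: float = 1.0):
        if length <= 0:
            raise ValueError("interval length must be positive")
        self.length = float(length)

    @property
    def measure(self) -> float:
        return self.length

    @property
    def diameter(self) -> float:
        return self.length

    def contains(self, x) -> np.ndarray | bool:
        x = np.asarray(x, dtype=float)
        return (x >= -_HALFPLANE_TOL) & (x <= self.length + _HALFPLANE_TOL)

    def uniform_sample(self, n: int, seed=None) -> np.ndarray:
        return _as_rng(seed).uniform(0.0, self.length, size=n)

    def __repr__(self):
        return f"Interval(length={self.length})"


class ConvexPolygon:
    """Convex polygon given by its vertices.

    Vertices are normalised to counter-clockwise order on construction
    (clockwise input is silently reversed, logged at DEBUG); a
    non-convex vertex list is rejected.  Point membership uses the
    half-plane representation: for each directed edge, the signed cross
    product with the query point must be >= -1e-12.
    """

    dim = 2

    def __init__(self, vertices):
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("need at least 3 vertices of shape (n, 2)")
        if np.any(np.all(np.isclose(verts, np.roll(verts, -1, axis=0)), axis=1)):
            raise ValueError("repeated consecutive vertices")
        signed2 = np.sum(
            verts[:, 0] * np.roll(verts[:, 1], -1) - np.roll(verts[:, 0], -1) * verts[:, 1]
        )
        if signed2 < 0:
            logger.debug("clockwise vertex order reversed to counter-clockwise")
            verts = verts[::-1]
            signed2 = -signed2
        if signed2 <= 0:
            raise ValueError("polygon has non-positive area")
        edges = np.roll(verts, -1, axis=0) - verts
        cross = edges[:, 0] * np.roll(edges, -1, axis=0)[:, 1] - edges[:, 1] * np.roll(edges, -1, axis=0)[:, 0]
        if np.any(cross < -1e-9 * np.max(np.abs(verts))):
            raise ValueError("vertex list is not convex")
        self.vertices = verts
        self._edges = edges
        self._area = 0.5 * signed2

    @property
    def measure(self) -> float:
        return self._area

    @property
    def diameter(self) -> float:
        v = self.vertices
        d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))

    @property
    def shapely(self) -> _ShapelyPolygon:
        if not hasattr(self, "_shapely"):
            self._shapely = _ShapelyPolygon(self.vertices)
        return self._shapely

    def contains(self, points) -> np.ndarray | bool:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        rel = pts[:, None, :] - self.vertices[None, :, :]  # (m, nv, 2)
        cross = self._edges[None, :, 0] * rel[:, :, 1] - self._edges[None, :, 1] * rel[:, :, 0]
        inside = np.all(cross >= -_HALFPLANE_TOL, axis=1)
        return bool(inside[0]) if single else inside

    def translate(self, dx: float, dy: float) -> "ConvexPolygon":
        return ConvexPolygon(self.vertices + np.array([dx, dy]))

    def bounding_box(self):
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return lo, hi

    def uniform_sample(self, n: int, seed=None) -> np.ndarray:
        """Rejection sampling from the bounding box."""
        rng = _as_rng(seed)
        lo, hi = self.bounding_box()
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 64)
            cand = rng.uniform(lo, hi, size=(m, 2))
            keep = cand[self.contains(cand)]
            take = min(len(keep), n - filled)
            out[filled : filled + take] = keep[:take]
            filled += take
        return out

    def __repr__(self):
        return f"ConvexPolygon({len(self.vertices)} vertices, area={self._area:.4g})"


def unit_square() -> ConvexPolygon:
    return ConvexPolygon([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


def regular_polygon(n_sides: int, radius: float = 1.0, center=(0.0, 0.0)) -> ConvexPolygon:
    """Regular n-gon inscribed in the circle of given radius."""
    ang = 2.0 * np.pi * np.arange(n_sides) / n_sides
    cx, cy = center
    return ConvexPolygon(np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)]))


class Disk:
    dim = 2

    def __init__(self, radius: float = 1.0, center=(0.0, 0.0)):
        if radius <= 0:
            raise ValueError("disk radius must be positive")
        self.radius = float(radius)
        self.center = np.asarray(center, dtype=float)

    @property
    def measure(self) -> float:
        return np.pi * self.radius**2

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, points) -> np.ndarray | bool:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        r2 = np.sum((pts - self.center) ** 2, axis=1)
        inside = r2 <= self.radius**2 * (1.0 + 1e-12)
        return bool(inside[0]) if single else inside

    def uniform_sample(self, n: int, seed=None) -> np.ndarray:
        rng = _as_rng(seed)
        r = self.radius * np.sqrt(rng.random(n))
        th = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return self.center + np.column_stack([r * np.cos(th), r * np.sin(th)])

    def __repr__(self):
        return f"Disk(radius={self.radius}, center={tuple(self.center)})"


# ---------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------

def contains(domain, point):
    return domain.contains(point)


def area(domain) -> float:
    """Measure of the domain (length in 1D, area in 2D)."""
    return domain.measure


def diameter(domain) -> float:
    return domain.diameter


def uniform_sample(domain, n: int, seed=None) -> np.ndarray:
    return domain.uniform_sample(n, seed)


def clip_intersection(poly_a: ConvexPolygon, poly_b: ConvexPolygon):
    """Intersection of two convex polygons, or ``None`` if (near-)empty.

    Successive half-plane clipping via shapely; the result of
    intersecting convex sets is convex.
    """
    inter = poly_a.shapely.intersection(poly_b.shapely)
    if inter.is_empty or inter.area <= 0.0 or inter.geom_type != "Polygon":
        return None
    coords = np.asarray(inter.exterior.coords)[:-1]
    return ConvexPolygon(coords)


def reflect_fold_1d(x, length: float = 1.0):
    """Fold a coordinate into [0, L] by repeated specular reflection.

    The fold map is periodic with period 2L: y = x mod 2L, then
    y -> 2L - y if y > L.  It is the image map underlying the
    method-of-images expansion of the reflecting step kernel.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    x = np.asarray(x, dtype=float)
    y = np.mod(x, 2.0 * length)
    y = np.where(y > length, 2.0 * length - y, y)
    if y.ndim == 0:
        return float(y)
    return y
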