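"""Geometry-specific shaper functions (set covariance of the domain).

Under no-go boundaries the empirically observed step density is the
intrinsic one multiplied by the *shaper function*

    h(l) = measure( Omega intersect (Omega - l) ),

the overlap between the domain and its translate by the step l (the set
covariance, or covariogram, of the domain).  It equals the domain
measure at l = 0, vanishes once |l| reaches the diameter, and for a
convex domain decreases monotonically along every ray from the origin.

Closed forms are provided for the interval, the unit square and the
unit-radius disk; arbitrary convex polygons go through exact polygon
clipping, and a brute-force grid-integration oracle is available for
testing.  Shaper values are exposed un-normalised (as overlap
lengths/areas), since every downstream use divides by an explicit
normalisation constant.
"""

from __future__ import annotations

import numpy as np

from .geometry import ConvexPolygon, Disk, Interval, clip_intersection

__all__ = [
    "shaper_interval",
    "shaper_square",
    "shaper_circle",
    "shaper_polygon",
    "grid_overlap_oracle",
    "magnitude_shaper",
    "ShaperFunction",
    "shaper_for",
]


def shaper_interval(ell, length: float = 1.0):
    """Overlap length (L - |l|) theta(L - |l|) of [0, L] with its translate."""
    ell = np.asarray(ell, dtype=float)
    return np.maximum(length - np.abs(ell), 0.0)


def shaper_square(lx, ly):
    """Unit-square set covariance: product of two interval shapers."""
    return shaper_interval(lx, 1.0) * shaper_interval(ly, 1.0)


def shaper_circle(lx, ly):
    """Unit-radius disk set covariance: lens area of two unit disks.

    h(l) = 2 arccos(|l|/2) - (1/2) sqrt((4 - |l|^2) |l|^2), zero for
    |l| >= 2.
    """
    s = np.hypot(np.asarray(lx, dtype=float), np.asarray(ly, dtype=float))
    s = np.minimum(s, 2.0)
    val = 2.0 * np.arccos(s / 2.0) - 0.5 * np.sqrt((4.0 - s * s) * s * s)
    return np.maximum(val, 0.0)


def shaper_disk(ell, radius: float = 1.0):
    """Set covariance of a disk of radius R at centre distance |l| (scales as R^2)."""
    ell = np.asarray(ell, dtype=float)
    return radius**2 * shaper_circle(ell / radius, 0.0)


def shaper_polygon(poly: ConvexPolygon, lx: float, ly: float) -> float:
    """Exact overlap area of a convex polygon with its translate by (lx, ly)."""
    shifted = poly.translate(-float(lx), -float(ly))
    inter = clip_intersection(poly, shifted)
    return 0.0 if inter is None else inter.measure


def grid_overlap_oracle(domain, lx: float, ly: float, n: int = 400) -> float:
    """Brute-force overlap area by indicator-product integration (test oracle).

    Midpoint rule on an n x n grid over the domain's bounding box.
    """
    if isinstance(domain, ConvexPolygon):
        lo, hi = domain.bounding_box()
    elif isinstance(domain, Disk):
        lo = domain.center - domain.radius
        hi = domain.center + domain.radius
    else:
        raise TypeError("grid oracle supports 2D domains only")
    xs = np.linspace(lo[0], hi[0], n, endpoint=False) + (hi[0] - lo[0]) / (2 * n)
    ys = np.linspace(lo[1], hi[1], n, endpoint=False) + (hi[1] - lo[1]) / (2 * n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = domain.contains(pts) & domain.contains(pts + np.array([lx, ly]))
    cell = (hi[0] - lo[0]) * (hi[1] - lo[1]) / (n * n)
    return float(np.count_nonzero(inside) * cell)


def magnitude_shaper(h_vector, ell, n_angles: int = 720):
    """Angular integral of a vector shaper at radius l.

    h_tilde(l) = integral over theta in [0, 2 pi) of h(l cos t, l sin t),
    by trapezoidal quadrature.  Set covariance is centrally symmetric
    (h(l) = h(-l)), so the integral over [0, pi) is computed and doubled.
    """
    if n_angles < 64:
        raise ValueError("n_angles must be >= 64")
    ell = np.asarray(ell, dtype=float)
    if np.any(ell < 0):
        raise ValueError("step magnitude must be nonnegative")
    theta = np.linspace(0.0, np.pi, n_angles // 2, endpoint=False)
    lx = ell[..., None] * np.cos(theta)
    ly = ell[..., None] * np.sin(theta)
    vals = h_vector(lx, ly)
    # periodic integrand sampled uniformly: rectangle rule == trapezoid
    return 2.0 * vals.mean(axis=-1) * np.pi


class ShaperFunction:
    """Shaper of a specific domain: vector form h(l) and magnitude form h_tilde(l).

    Dispatches to the closed form for intervals, unit squares and disks,
    and to exact polygon clipping otherwise.  ``cutoff`` is the domain
    diameter, beyond which the shaper is identically zero.
    """

    def __init__(self, domain, n_angles: int = 720):
        self.domain = domain
        self.cutoff = domain.diameter
        self.n_angles = int(n_angles)
        if isinstance(domain, Interval):
            self.mode = "closed_form_interval"
        elif isinstance(domain, Disk):
            self.mode = "closed_form_circle"
        elif isinstance(domain, ConvexPolygon):
            self.mode = (
                "closed_form_square" if self._is_unit_square(domain) else "polygon_covariance"
            )
        else:
            raise TypeError(f"unsupported domain {domain!r}")

    @staticmethod
    def _is_unit_square(poly: ConvexPolygon) -> bool:
        if poly.vertices.shape[0] != 4:
            return False
        v = np.array(sorted(map(tuple, poly.vertices.round(12))))
        ref = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        return np.allclose(v, ref)

    @property
    def h0(self) -> float:
        """Value at zero step: the domain measure."""
        return self.domain.measure

    def vector(self, lx, ly=None):
        """h at a step vector; for intervals pass the signed step as ``lx``."""
        if self.mode == "closed_form_interval":
            return shaper_interval(lx, self.domain.length)
        if self.mode == "closed_form_square":
            return shaper_square(lx, ly)
        if self.mode == "closed_form_circle":
            r = self.domain.radius
            return r * r * shaper_circle(np.asarray(lx, dtype=float) / r, np.asarray(ly, dtype=float) / r)
        # polygon covariance: exact clipping, scalar loop
        lx = np.asarray(lx, dtype=float)
        ly = np.asarray(ly, dtype=float)
        lx_b, ly_b = np.broadcast_arrays(lx, ly)
        out = np.empty(lx_b.shape)
        it = np.nditer(lx_b, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            out[idx] = shaper_polygon(self.domain, lx_b[idx], ly_b[idx])
        return out if out.ndim else float(out)

    __call__ = vector

    def magnitude(self, ell, n_angles: int | None = None):
        """Angular-integrated shaper h_tilde(l) (2D domains only)."""
        if self.domain.dim != 2:
            raise ValueError("magnitude shaper is defined for 2D domains")
        ell = np.asarray(ell, dtype=float)
        if self.mode == "closed_form_circle":
            # integrand is constant in angle by rotational symmetry
            return 2.0 * np.pi * self.vector(ell, np.zeros_like(ell))
        return magnitude_shaper(self.vector, ell, n_angles or self.n_angles)


def shaper_for(domain, n_angles: int = 720) -> ShaperFunction:
    return ShaperFunction(domain, n_angles=n_angles)
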