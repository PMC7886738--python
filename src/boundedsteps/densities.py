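"""Stationary stopping densities and transformed (empirical) step densities.

The stationary stopping-location density g solves the homogeneous
Fredholm equation of the second kind

    g(x) = integral over x' of g(x') P(x - x' | x'),

with P the boundary-condition-specific step kernel.  Under no-go
boundaries g is proportional to the acceptance mass N(x) — the
probability that an unconstrained step from x lands inside the domain —
and the observed step density factorises as f_t = f_i * h / Z with h the
domain's shaper function.  A Nystrom discretisation with power iteration
is provided as an independent numerical check of these closed forms, and
as the only available route for the stop-go stationary density, which
has no closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .distributions import StepDistribution1D, StepDistribution2D
from .geometry import ConvexPolygon, Disk, Interval
from .shaper import ShaperFunction, shaper_for

__all__ = [
    "GridDensity",
    "FredholmSolution",
    "NormalisedDensity",
    "normalisation_N",
    "gamma_circle",
    "stopping_density_nogo",
    "transition_matrix_1d",
    "fredholm_solve",
    "transformed_pdf_nogo",
    "transformed_pdf_nogo_magnitude",
    "transformed_pdf_stopgo_1d",
    "transformed_pdf_reflecting_1d",
]


@dataclass
class GridDensity:
    """Density tabulated on a grid with quadrature weights."""

    grid: np.ndarray
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("density values must be nonnegative")

    def integral(self) -> float:
        return float(self.weights @ self.values)

    def normalised(self) -> "GridDensity":
        return GridDensity(self.grid, self.values / self.integral(), self.weights)

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self.grid, self.values)


@dataclass
class FredholmSolution(GridDensity):
    residual: float = np.nan
    iterations: int = 0


class NormalisedDensity:
    """Callable density f(x) = raw(x) / Z on [lo, hi], Z by quadrature."""

    def __init__(self, raw, lo: float, hi: float, points=None):
        self.raw = raw
        self.lo = float(lo)
        self.hi = float(hi)
        z, _ = integrate.quad(raw, lo, hi, limit=400, points=points, epsabs=1e-11)
        if z <= 0:
            raise ValueError("density has nonpositive mass on its support")
        self.norm = z

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.asarray(self.raw(x), dtype=float) / self.norm
        return np.where((x >= self.lo) & (x <= self.hi), out, 0.0)

    __call__ = pdf

    def moment(self, k: int) -> float:
        val, _ = integrate.quad(lambda x: x**k * self.pdf(x), self.lo, self.hi, limit=400)
        return val

    def second_moment(self) -> float:
        return self.moment(2)

    def variance(self) -> float:
        m1 = self.moment(1)
        return self.second_moment() - m1 * m1


# ---------------------------------------------------------------------
# acceptance mass N
# ---------------------------------------------------------------------

def gamma_circle(R: float, ell: float) -> float:
    """Fraction of the circle of radius ell around a point at radius R
    (from the centre of the unit disk) that lies inside the disk:
    gamma(R, l) = arccos((R^2 + l^2 - 1) / (2 R l)) / pi."""
    arg = (R * R + ell * ell - 1.0) / (2.0 * R * ell)
    return float(np.arccos(np.clip(arg, -1.0, 1.0)) / np.pi)


def _nogo_acceptance_disk(dist: StepDistribution2D, r: float, radius: float = 1.0) -> float:
    """N at distance r from the centre of a disk of given radius."""
    # work in units of the disk radius applied to the geometry only
    def integrand(ell):
        mag = dist.magnitude_pdf(ell)
        if ell <= radius - r:
            return mag
        gam = gamma_circle(r / radius, ell / radius)
        return mag * gam

    upper = min(dist._effective_radius(), r + radius)
    if upper <= 0:
        return 0.0
    pts = [abs(radius - r)] if abs(radius - r) < upper else None
    val, _ = integrate.quad(integrand, 0.0, upper, limit=400, points=pts)
    return float(val)


def normalisation_N(domain, dist, r):
    """Probability that an unconstrained step from ``r`` lands inside the domain.

    1D intervals use the step law's CDF; disks use the radial overlap
    fraction gamma; convex polygons fall back to quadrature of the step
    law over the (shifted) polygon on a Cartesian grid.
    """
    if isinstance(domain, Interval):
        x = np.asarray(r, dtype=float)
        return dist.cdf(domain.length - x) - dist.cdf(-x)
    if isinstance(domain, Disk):
        rr = np.atleast_1d(np.asarray(r, dtype=float))
        if rr.ndim == 2:  # points given as coordinates
            rr = np.linalg.norm(rr - domain.center, axis=1)
        out = np.array([_nogo_acceptance_disk(dist, float(v), domain.radius) for v in rr])
        return out if out.size > 1 else float(out[0])
    if isinstance(domain, ConvexPolygon):
        pt = np.asarray(r, dtype=float)
        if pt.ndim == 1:
            return _nogo_acceptance_polygon(domain, dist, pt)
        return np.array([_nogo_acceptance_polygon(domain, dist, p) for p in pt])
    raise TypeError(f"unsupported domain {domain!r}")


def _polygon_acceptance_batch(
    poly: ConvexPolygon, dist: StepDistribution2D, pts: np.ndarray, n: int = 128
) -> np.ndarray:
    """Acceptance mass at many start points via one shared destination grid."""
    lo, hi = poly.bounding_box()
    xs = np.linspace(lo[0], hi[0], n, endpoint=False) + (hi[0] - lo[0]) / (2 * n)
    ys = np.linspace(lo[1], hi[1], n, endpoint=False) + (hi[1] - lo[1]) / (2 * n)
    gx, gy = np.meshgrid(xs, ys)
    dest = np.column_stack([gx.ravel(), gy.ravel()])
    dest = dest[poly.contains(dest)]
    cell = (hi[0] - lo[0]) * (hi[1] - lo[1]) / (n * n)
    out = np.empty(len(pts))
    chunk = max(1, 2_000_000 // max(len(dest), 1))
    for i in range(0, len(pts), chunk):
        block = pts[i : i + chunk]
        d = dest[None, :, :] - block[:, None, :]
        out[i : i + chunk] = dist.radial_profile(np.hypot(d[..., 0], d[..., 1])).sum(axis=1) * cell
    return out


def _nogo_acceptance_polygon(
    poly: ConvexPolygon, dist: StepDistribution2D, pt: np.ndarray, n: int = 256
) -> float:
    lo, hi = poly.bounding_box()
    xs = np.linspace(lo[0], hi[0], n, endpoint=False) + (hi[0] - lo[0]) / (2 * n)
    ys = np.linspace(lo[1], hi[1], n, endpoint=False) + (hi[1] - lo[1]) / (2 * n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = poly.contains(pts)
    dens = dist.pdf(pts[inside, 0] - pt[0], pts[inside, 1] - pt[1])
    cell = (hi[0] - lo[0]) * (hi[1] - lo[1]) / (n * n)
    return float(dens.sum() * cell)


# ---------------------------------------------------------------------
# stationary stopping densities (no-go closed form)
# ---------------------------------------------------------------------

def stopping_density_nogo(domain, dist, grid_n: int = 201) -> GridDensity:
    """Stationary stopping density g under no-go boundaries: g proportional to N.

    Intervals: g(x) on a uniform grid.  Disks: radial density g(r) on a
    radius grid, normalised with the polar weight 2 pi r.  Polygons are
    supported through :func:`normalisation_N` on a caller-supplied grid.
    """
    if isinstance(domain, Interval):
        grid = np.linspace(0.0, domain.length, grid_n)
        vals = normalisation_N(domain, dist, grid)
        w = _trapezoid_weights(grid)
        return GridDensity(grid, vals, w).normalised()
    if isinstance(domain, Disk):
        grid = np.linspace(0.0, domain.radius, grid_n)
        vals = np.array([_nogo_acceptance_disk(dist, r, domain.radius) for r in grid])
        w = _trapezoid_weights(grid) * 2.0 * np.pi * grid
        dens = GridDensity(grid, vals, w)
        return dens.normalised()
    if isinstance(domain, ConvexPolygon):
        # slower path: acceptance mass on a 2D midpoint grid over the polygon
        import logging

        logging.getLogger(__name__).info(
            "polygon stopping density: 2D quadrature on a %dx%d grid", grid_n, grid_n
        )
        lo, hi = domain.bounding_box()
        xs = np.linspace(lo[0], hi[0], grid_n, endpoint=False) + (hi[0] - lo[0]) / (2 * grid_n)
        ys = np.linspace(lo[1], hi[1], grid_n, endpoint=False) + (hi[1] - lo[1]) / (2 * grid_n)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts = pts[domain.contains(pts)]
        cell = (hi[0] - lo[0]) * (hi[1] - lo[1]) / (grid_n * grid_n)
        vals = _polygon_acceptance_batch(domain, dist, pts)
        w = np.full(len(pts), cell)
        return GridDensity(pts, vals, w).normalised()
    raise TypeError(f"unsupported domain {domain!r}")


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


# ---------------------------------------------------------------------
# Nystrom / power-iteration Fredholm solver
# ---------------------------------------------------------------------

def transition_matrix_1d(
    domain: Interval, dist: StepDistribution1D, bc: str, grid: np.ndarray
) -> np.ndarray:
    """Column-stochastic transition matrix T[i, j]: mass moved from source
    node x_j into the destination cell around x_i in one step.

    Destination integration is exact — cell masses are CDF differences —
    so discontinuous step laws lose no accuracy; only the source
    discretisation (one node per cell) is approximate.  Stop-go boundary
    atoms are point masses added to the two end cells.  Every column sums
    to one to within round-off.
    """
    L = domain.length
    mid = 0.5 * (grid[:-1] + grid[1:])
    lo = np.concatenate(([grid[0]], mid))[:, None]   # destination cell edges
    hi = np.concatenate((mid, [grid[-1]]))[:, None]
    x = grid[None, :]                                 # source nodes
    if bc in ("no_go", "stop_go"):
        T = dist.cdf(hi - x) - dist.cdf(lo - x)
        if bc == "stop_go":
            T[0, :] += dist.cdf(-grid)            # truncated at the left wall
            T[-1, :] += 1.0 - dist.cdf(L - grid)  # truncated at the right wall
        else:
            T = T / T.sum(axis=0, keepdims=True)  # rejection renormalisation
    elif bc == "reflecting":
        R = dist.support_radius if np.isfinite(dist.support_radius) else dist._effective_radius()
        kmax = int(np.ceil((R + 2.0 * L) / (2.0 * L))) + 1
        T = np.zeros((len(grid), len(grid)))
        for k in range(-kmax, kmax + 1):
            s = 2.0 * k * L
            T += dist.cdf(s + hi - x) - dist.cdf(s + lo - x)      # direct images
            T += dist.cdf(s - lo - x) - dist.cdf(s - hi - x)      # folded images
    else:
        raise ValueError(f"unknown boundary condition {bc!r}")
    return T


def fredholm_solve(
    domain,
    dist,
    bc: str = "no_go",
    grid_n: int = 201,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> FredholmSolution:
    """Stationary stopping density by Nystrom discretisation + power iteration.

    Supports 1D intervals under all three boundary conditions and the
    disk (radial reduction) under no-go.  Outgoing transition mass per
    source node is renormalised to exactly one after discretisation, so
    the discrete chain conserves probability; the stationary vector is
    found by power iteration from a uniform start and reported with the
    sup-norm residual of g - Kg.
    """
    if isinstance(domain, Interval):
        # solve on an internally refined grid: kinks and jumps of the step
        # law contribute O(h) node errors, so refine then subsample
        refine = 4
        grid = np.linspace(0.0, domain.length, (grid_n - 1) * refine + 1)
        w = _trapezoid_weights(grid)
        T = transition_matrix_1d(domain, dist, bc, grid)
        colsum = T.sum(axis=0)
        if np.any(colsum <= 0):
            raise RuntimeError("transition kernel has a source node with zero outgoing mass")
        T = T / colsum[None, :]
        g_mass = np.full(grid.size, 1.0 / grid.size)
        it, diff = 0, np.inf
        while diff > tol and it < max_iter:
            g_new = T @ g_mass
            g_new /= g_new.sum()
            diff = np.max(np.abs(g_new - g_mass))
            g_mass = g_new
            it += 1
        if diff > tol:
            lam = np.sort(np.abs(np.linalg.eigvals(T)))[-2:]
            raise RuntimeError(
                f"power iteration did not converge in {max_iter} iterations "
                f"(residual {diff:.2e}; leading |eigenvalues| {lam})"
            )
        # cell masses -> node densities; the half-width end cells average the
        # density over [0, h/2], so extrapolate linearly from the centroids
        dens_cell = g_mass / w
        c = grid.copy()
        c[0] += w[0] / 2.0
        c[-1] -= w[-1] / 2.0  # cell centroids (interior cells are node-centred)
        dens = np.interp(grid, c, dens_cell)
        dens[0] = dens_cell[0] + (grid[0] - c[0]) * (dens_cell[1] - dens_cell[0]) / (c[1] - c[0])
        dens[-1] = dens_cell[-1] + (grid[-1] - c[-1]) * (dens_cell[-1] - dens_cell[-2]) / (
            c[-1] - c[-2]
        )
        dens = np.maximum(dens, 0.0)
        resid = float(np.max(np.abs(T @ g_mass - g_mass)))
        grid_out = grid[::refine]
        w_out = _trapezoid_weights(grid_out)
        dens_out = dens[::refine]
        dens_out = dens_out / (w_out @ dens_out)
        return FredholmSolution(
            grid=grid_out, values=dens_out, weights=w_out, residual=resid, iterations=it
        )

    if isinstance(domain, Disk):
        if bc != "no_go":
            raise ValueError("disk Fredholm solver supports no-go boundaries only")
        return _fredholm_disk_nogo(domain, dist, grid_n, tol, max_iter)

    raise TypeError("fredholm_solve supports intervals (all bcs) and disks (no-go)")


def _fredholm_disk_nogo(
    domain: Disk, dist: StepDistribution2D, grid_n: int, tol: float, max_iter: int,
    n_angles: int = 256,
) -> FredholmSolution:
    """Radial Nystrom reduction of the 2D no-go kernel on a disk.

    By rotational symmetry the stationary density depends on the radius
    alone; the angular integral of the planar step density between radii
    r' and r is computed by trapezoidal quadrature.
    """
    R = domain.radius
    grid = np.linspace(0.0, R, grid_n)
    w = _trapezoid_weights(grid) * 2.0 * np.pi * grid  # polar measure weights
    theta = np.linspace(0.0, np.pi, n_angles, endpoint=False) + np.pi / (2 * n_angles)
    ct = np.cos(theta)
    # angular average of f_i(|r - r'|): distance(r, r', theta)
    r_dst = grid[:, None, None]
    r_src = grid[None, :, None]
    d = np.sqrt(np.maximum(r_dst**2 + r_src**2 - 2.0 * r_dst * r_src * ct[None, None, :], 0.0))
    K = dist.radial_profile(d).mean(axis=2)  # (dst, src) angular mean
    T = K * w[:, None]
    colsum = T.sum(axis=0)
    if np.any(colsum <= 0):
        raise RuntimeError("transition kernel has a source node with zero outgoing mass")
    T = T / colsum[None, :]
    g_mass = np.full(grid_n, 1.0 / grid_n)
    it, diff = 0, np.inf
    while diff > tol and it < max_iter:
        g_new = T @ g_mass
        g_new /= g_new.sum()
        diff = np.max(np.abs(g_new - g_mass))
        g_mass = g_new
        it += 1
    if diff > tol:
        raise RuntimeError(f"power iteration did not converge (residual {diff:.2e})")
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(w > 0, g_mass / w, 0.0)
    dens[0] = dens[1]  # r = 0 node carries zero polar weight; extend continuously
    dens /= w @ dens
    resid = float(np.max(np.abs(T @ g_mass - g_mass)))
    return FredholmSolution(grid=grid, values=dens, weights=w, residual=resid, iterations=it)


# ---------------------------------------------------------------------
# transformed step densities
# ---------------------------------------------------------------------

def transformed_pdf_nogo(dist: StepDistribution1D, shaper: ShaperFunction | Interval) -> NormalisedDensity:
    """1D no-go transformed step density: f_t = f_i * h / Z."""
    h = shaper if isinstance(shaper, ShaperFunction) else shaper_for(shaper)
    if h.domain.dim != 1:
        raise ValueError("use transformed_pdf_nogo_magnitude for 2D domains")
    cut = min(h.cutoff, dist.support_radius)
    if cut <= 0:
        raise ValueError("empty support")

    def raw(l):
        return dist.pdf(l) * h.vector(l)

    pts = [p for p in (-dist.support_radius, dist.support_radius) if np.isfinite(p) and abs(p) < cut]
    return NormalisedDensity(raw, -cut, cut, points=pts or None)


def transformed_pdf_nogo_magnitude(
    dist: StepDistribution2D, shaper: ShaperFunction, n_angles: int | None = None
) -> NormalisedDensity:
    """2D no-go transformed step-magnitude density.

    f~_t(l) proportional to f_i(l, 0) * l * h~(l), with h~ the
    angular-integrated shaper of the domain.
    """
    cut = min(shaper.cutoff, dist.support_radius)
    if cut <= 0:
        raise ValueError("empty support")
    if shaper.mode == "polygon_covariance":
        # clipping is expensive: pre-tabulate the magnitude shaper
        grid = np.linspace(0.0, cut, 1024)
        hvals = shaper.magnitude(grid, n_angles)

        def h_of(l):
            return np.interp(l, grid, hvals)

    else:

        def h_of(l):
            return shaper.magnitude(l, n_angles)

    def raw(l):
        l = np.asarray(l, dtype=float)
        return dist.radial_profile(l) * l * h_of(l)

    pts = [dist.support_radius] if np.isfinite(dist.support_radius) and dist.support_radius < cut else None
    return NormalisedDensity(raw, 0.0, cut, points=pts)


def transformed_pdf_stopgo_1d(dist: StepDistribution1D, length: float = 1.0) -> NormalisedDensity:
    """1D stop-go transformed step density under a uniform start.

    Assumes the walker is placed uniformly at random and only first-step
    statistics are collected (the stationary density has no closed
    form).  The boundary truncation smears the step kernel's boundary
    atoms into the continuous tail term:

        f_t(l) = f_i(l) h_1D(l) + (1 - F_i(|l|)) theta(L - |l|),

    with F_i the intrinsic CDF; the tail term is the symmetrised form of
    the two one-sided truncation integrals.
    """
    L = length

    def raw(l):
        l = np.asarray(l, dtype=float)
        al = np.abs(l)
        body = dist.pdf(l) * np.maximum(L - al, 0.0)
        tail = np.where(al < L, 1.0 - dist.cdf(al), 0.0)
        return body + tail

    return NormalisedDensity(raw, -L, L)


def transformed_pdf_reflecting_1d(
    dist: StepDistribution1D, length: float = 1.0, n_images: int | None = None
) -> NormalisedDensity:
    """1D reflecting transformed step density by the method of images.

    The stationary stopping density is uniform regardless of f_i.  With
    start x uniform on [0, L], the observed step l has density

        f_t(l) = int dx sum_k [ f_i(l + 2kL) + f_i(2kL - 2x - l) ],

    the x-range restricted so the landing point x + l lies in [0, L].
    The image sum is finite once 2 k L exceeds the support radius; for a
    support radius below 2L a single image suffices.
    """
    L = length
    R = dist.support_radius if np.isfinite(dist.support_radius) else dist._effective_radius()
    if n_images is None:
        # folded-image argument spans 2kL - (2x + l) with 2x + l in [-L, 3L]
        n_images = int(np.ceil((R + 3.0 * L) / (2.0 * L)))

    def raw(l):
        l = np.asarray(l, dtype=float)
        x_lo = np.maximum(0.0, -l)
        x_hi = np.minimum(L, L - l)
        width = np.maximum(x_hi - x_lo, 0.0)
        total = np.zeros_like(l)
        for k in range(-n_images, n_images + 1):
            # direct-image term is x-independent
            total += dist.pdf(l + 2.0 * k * L) * width
            # folded-image term integrates in x through the CDF
            a = 2.0 * k * L - 2.0 * x_hi - l
            b = 2.0 * k * L - 2.0 * x_lo - l
            total += np.where(width > 0, (dist.cdf(b) - dist.cdf(a)) / 2.0, 0.0)
        return total

    return NormalisedDensity(raw, -L, L)
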