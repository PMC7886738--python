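"""Intrinsic step-distribution families.

The intrinsic step law ``f_i`` is the displacement distribution a walker
would exhibit in unbounded space: symmetric about zero in 1D,
rotationally symmetric in 2D.  Enclosure in a bounded domain biases the
observed (empirical) step histogram away from ``f_i``; the rest of the
package quantifies and corrects that bias.

Shipped families
----------------
``parabolic``
    f_i(l) = 3 (a^2 - l^2) / (4 a^3) on [-a, a]; the 2D analogue uses the
    radial profile f_i(l, 0) = 2 (a^2 - l^2) / (pi a^4) on [0, a].
``gaussian``
    zero-mean normal with standard deviation ``sigma`` (per axis in 2D).
``uniform``
    flat on [-a, a] (1D) or on the disk of radius ``a`` (2D).
``tabulated``
    user-supplied (grid, density) table with linear interpolation, so
    empirically measured kernels can be plugged in.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "StepDistribution1D",
    "StepDistribution2D",
    "Parabolic1D",
    "Gaussian1D",
    "Uniform1D",
    "Tabulated1D",
    "Parabolic2D",
    "Gaussian2D",
    "Uniform2D",
    "Tabulated2D",
    "step_distribution",
    "pdf_1d",
    "sample_1d",
    "magnitude_pdf_2d",
    "sample_2d",
]

_INV_CDF_GRID = 4096  # nodes of the cached inverse-CDF table


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class StepDistribution1D:
    """Symmetric step law on the real line.

    Subclasses provide :meth:`pdf` and ``support_radius`` (``np.inf``
    allowed).  Sampling defaults to inverse-CDF lookup on a cached
    4096-node grid; families with exact samplers override :meth:`sample`.
    """

    family: str = "base"
    support_radius: float = np.inf

    def pdf(self, ell):
        raise NotImplementedError

    # -- cumulative distribution ------------------------------------
    def cdf(self, ell):
        grid, cums = self._cdf_table()
        return np.interp(np.asarray(ell, dtype=float), grid, cums, left=0.0, right=1.0)

    def _cdf_table(self):
        if not hasattr(self, "_cdf_cache"):
            r = self._effective_radius()
            grid = np.linspace(-r, r, _INV_CDF_GRID)
            dens = self.pdf(grid)
            cums = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
            cums /= cums[-1]
            self._cdf_cache = (grid, cums)
        return self._cdf_cache

    def _effective_radius(self) -> float:
        return float(self.support_radius)

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = _as_rng(seed)
        grid, cums = self._cdf_table()
        u = rng.random(n)
        return np.interp(u, cums, grid)

    def variance(self) -> float:
        r = self._effective_radius()
        val, _ = integrate.quad(lambda l: l * l * self.pdf(l), -r, r, limit=200)
        return val

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(support_radius={self.support_radius})"


class Parabolic1D(StepDistribution1D):
    """Concave-parabola kernel 3(a^2 - l^2)/(4 a^3) on [-a, a]."""

    family = "parabolic"

    def __init__(self, a: float = 0.75):
        if a <= 0:
            raise ValueError("half-support a must be positive")
        self.a = float(a)
        self.support_radius = self.a

    def pdf(self, ell):
        ell = np.asarray(ell, dtype=float)
        inside = np.abs(ell) < self.a  # Heaviside theta(0) = 0 convention
        out = np.where(inside, 3.0 * (self.a**2 - ell**2) / (4.0 * self.a**3), 0.0)
        return out

    def cdf(self, ell):
        ell = np.clip(np.asarray(ell, dtype=float), -self.a, self.a)
        a = self.a
        return 0.5 + (3.0 * a * a * ell - ell**3) / (4.0 * a**3)

    def variance(self) -> float:
        return self.a**2 / 5.0


class Gaussian1D(StepDistribution1D):
    family = "gaussian"

    def __init__(self, sigma: float = 0.5):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = float(sigma)
        self.support_radius = np.inf

    def pdf(self, ell):
        return stats.norm.pdf(np.asarray(ell, dtype=float), scale=self.sigma)

    def cdf(self, ell):
        return stats.norm.cdf(np.asarray(ell, dtype=float), scale=self.sigma)

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        return _as_rng(seed).normal(0.0, self.sigma, size=n)

    def variance(self) -> float:
        return self.sigma**2

    def _effective_radius(self) -> float:
        return 10.0 * self.sigma


class Uniform1D(StepDistribution1D):
    family = "uniform"

    def __init__(self, a: float = 1.0):
        if a <= 0:
            raise ValueError("half-support a must be positive")
        self.a = float(a)
        self.support_radius = self.a

    def pdf(self, ell):
        ell = np.asarray(ell, dtype=float)
        return np.where(np.abs(ell) < self.a, 1.0 / (2.0 * self.a), 0.0)

    def cdf(self, ell):
        ell = np.clip(np.asarray(ell, dtype=float), -self.a, self.a)
        return (ell + self.a) / (2.0 * self.a)

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        return _as_rng(seed).uniform(-self.a, self.a, size=n)

    def variance(self) -> float:
        return self.a**2 / 3.0


class Tabulated1D(StepDistribution1D):
    """Step law given on a grid, linearly interpolated and renormalised.

    The table need only cover ``l >= 0``; symmetry is enforced by
    evaluating at ``|l|``.
    """

    family = "tabulated"

    def __init__(self, grid: Sequence[float], density: Sequence[float]):
        grid = np.asarray(grid, dtype=float)
        density = np.asarray(density, dtype=float)
        if grid.ndim != 1 or grid.shape != density.shape or grid.size < 2:
            raise ValueError("grid and density must be matching 1D arrays")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(density < 0):
            raise ValueError("density values must be nonnegative")
        order = np.argsort(np.abs(grid))
        self._grid = np.abs(grid)[order]
        self._vals = density[order]
        # symmetrise: full-line mass is twice the half-line integral
        half = np.trapezoid(self._vals, self._grid)
        if half <= 0:
            raise ValueError("density must have positive mass")
        self._vals = self._vals / (2.0 * half)
        self.support_radius = float(self._grid[-1])

    def pdf(self, ell):
        ell = np.abs(np.asarray(ell, dtype=float))
        out = np.interp(ell, self._grid, self._vals, left=0.0, right=0.0)
        return np.where(ell < self.support_radius, out, 0.0)


class StepDistribution2D:
    """Rotationally symmetric planar step law.

    Defined by the radial profile ``f_i(l, 0)`` — the planar density at
    distance ``l`` from the origin.  The induced step-magnitude density is
    ``2 pi l f_i(l, 0)``.
    """

    family: str = "base"
    support_radius: float = np.inf

    def radial_profile(self, ell):
        """Planar density f_i(l, 0) at magnitude l."""
        raise NotImplementedError

    def pdf(self, lx, ly):
        """Planar density at the step vector (lx, ly)."""
        return self.radial_profile(np.hypot(lx, ly))

    def magnitude_pdf(self, ell):
        ell = np.asarray(ell, dtype=float)
        if np.any(ell < 0):
            raise ValueError("step magnitude must be nonnegative")
        return 2.0 * np.pi * ell * self.radial_profile(ell)

    def _effective_radius(self) -> float:
        return float(self.support_radius)

    def _magnitude_cdf_table(self):
        if not hasattr(self, "_mag_cache"):
            r = self._effective_radius()
            grid = np.linspace(0.0, r, _INV_CDF_GRID)
            cums = integrate.cumulative_trapezoid(self.magnitude_pdf(grid), grid, initial=0.0)
            cums /= cums[-1]
            self._mag_cache = (grid, cums)
        return self._mag_cache

    def magnitude_cdf(self, ell):
        grid, cums = self._magnitude_cdf_table()
        return np.interp(np.asarray(ell, dtype=float), grid, cums, left=0.0, right=1.0)

    def sample_magnitude(self, n: int, rng: np.random.Generator) -> np.ndarray:
        grid, cums = self._magnitude_cdf_table()
        return np.interp(rng.random(n), cums, grid)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """n i.i.d. step vectors, shape (n, 2): uniform direction, inverse-CDF magnitude."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = _as_rng(seed)
        mag = self.sample_magnitude(n, rng)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([mag * np.cos(theta), mag * np.sin(theta)])

    def second_moment(self) -> float:
        """E[|l|^2] of the step magnitude."""
        r = self._effective_radius()
        val, _ = integrate.quad(lambda l: l * l * self.magnitude_pdf(l), 0.0, r, limit=200)
        return val


class Parabolic2D(StepDistribution2D):
    """Radial profile 2(a^2 - l^2)/(pi a^4) on [0, a] (unit planar mass)."""

    family = "parabolic"

    def __init__(self, a: float = 0.75):
        if a <= 0:
            raise ValueError("half-support a must be positive")
        self.a = float(a)
        self.support_radius = self.a

    def radial_profile(self, ell):
        ell = np.asarray(ell, dtype=float)
        return np.where(
            np.abs(ell) < self.a,
            2.0 * (self.a**2 - ell**2) / (np.pi * self.a**4),
            0.0,
        )


class Gaussian2D(StepDistribution2D):
    """Isotropic bivariate normal; magnitude is Rayleigh(sigma)."""

    family = "gaussian"

    def __init__(self, sigma: float = 0.5):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = float(sigma)
        self.support_radius = np.inf

    def radial_profile(self, ell):
        ell = np.asarray(ell, dtype=float)
        s2 = self.sigma**2
        return np.exp(-(ell**2) / (2.0 * s2)) / (2.0 * np.pi * s2)

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        return _as_rng(seed).normal(0.0, self.sigma, size=(n, 2))

    def second_moment(self) -> float:
        return 2.0 * self.sigma**2

    def _effective_radius(self) -> float:
        return 10.0 * self.sigma


class Uniform2D(StepDistribution2D):
    """Uniform step vector on the disk of radius a."""

    family = "uniform"

    def __init__(self, a: float = 1.0):
        if a <= 0:
            raise ValueError("radius a must be positive")
        self.a = float(a)
        self.support_radius = self.a

    def radial_profile(self, ell):
        ell = np.asarray(ell, dtype=float)
        return np.where(np.abs(ell) < self.a, 1.0 / (np.pi * self.a**2), 0.0)

    def sample_magnitude(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.a * np.sqrt(rng.random(n))

    def second_moment(self) -> float:
        return self.a**2 / 2.0


class Tabulated2D(StepDistribution2D):
    """Radial profile f_i(l, 0) tabulated on a magnitude grid, renormalised."""

    family = "tabulated"

    def __init__(self, grid: Sequence[float], profile: Sequence[float]):
        grid = np.asarray(grid, dtype=float)
        profile = np.asarray(profile, dtype=float)
        if grid.ndim != 1 or grid.shape != profile.shape or grid.size < 2:
            raise ValueError("grid and profile must be matching 1D arrays")
        if grid[0] < 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be nonnegative and strictly increasing")
        if np.any(profile < 0):
            raise ValueError("profile values must be nonnegative")
        # exact planar mass of the linear interpolant: on each segment the
        # profile is a*l + b, so 2 pi l * profile integrates in closed form
        l1, l2 = grid[:-1], grid[1:]
        p1, p2 = profile[:-1], profile[1:]
        a = (p2 - p1) / (l2 - l1)
        b = p1 - a * l1
        mass = float(
            2.0 * np.pi * np.sum(a * (l2**3 - l1**3) / 3.0 + b * (l2**2 - l1**2) / 2.0)
        )
        if mass <= 0:
            raise ValueError("profile must have positive planar mass")
        self._grid = grid
        self._vals = profile / mass
        self.support_radius = float(grid[-1])

    def radial_profile(self, ell):
        ell = np.abs(np.asarray(ell, dtype=float))
        out = np.interp(ell, self._grid, self._vals, left=0.0, right=0.0)
        return np.where(ell < self.support_radius, out, 0.0)


_FAMILIES_1D: dict[str, Callable] = {
    "parabolic": Parabolic1D,
    "gaussian": Gaussian1D,
    "uniform": Uniform1D,
    "tabulated": Tabulated1D,
}
_FAMILIES_2D: dict[str, Callable] = {
    "parabolic": Parabolic2D,
    "gaussian": Gaussian2D,
    "uniform": Uniform2D,
    "tabulated": Tabulated2D,
}


def step_distribution(family: str, dim: int = 1, **params):
    """Build a step distribution by family name and dimension.

    Raises ``ValueError`` for an unknown family (configuration error).
    """
    table = {1: _FAMILIES_1D, 2: _FAMILIES_2D}.get(dim)
    if table is None:
        raise ValueError(f"unsupported dimension {dim}")
    try:
        cls = table[family]
    except KeyError:
        raise ValueError(
            f"unknown step-distribution family {family!r}; "
            f"choose from {sorted(table)}"
        ) from None
    return cls(**params)


# ---------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------

def pdf_1d(dist: StepDistribution1D, ell):
    """Intrinsic 1D step density f_i(l)."""
    return dist.pdf(ell)


def sample_1d(dist: StepDistribution1D, n: int, seed=None) -> np.ndarray:
    """n i.i.d. draws from f_i, reproducible given ``seed``."""
    return dist.sample(n, seed)


def magnitude_pdf_2d(dist: StepDistribution2D, ell):
    """Step-magnitude density 2 pi l f_i(l, 0)."""
    return dist.magnitude_pdf(ell)


def sample_2d(dist: StepDistribution2D, n: int, seed=None) -> np.ndarray:
    """n i.i.d. planar step vectors, shape (n, 2)."""
    return dist.sample(n, seed)
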