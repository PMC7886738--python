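"""Ensemble simulation of intermittent locomotion in a bounded domain.

Each run starts uniformly at random in the domain and performs N steps
drawn from the intrinsic step law, handled at the boundary according to
one of three conditions:

``no_go``
    a proposed step landing outside the domain is rejected and the whole
    step (direction and magnitude) redrawn, as often as needed;
``stop_go``
    the proposed segment is truncated at its first boundary crossing and
    the walker stops exactly on the boundary (1D only);
``reflecting``
    the landing point is folded back into the domain by specular
    reflection, repeated if the overshoot spans multiple domain lengths
    (1D only).

All M runs are advanced in lockstep from a single seeded generator, so
an ensemble is reproducible from (domain, distribution, N, M, seed)
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import StepDistribution1D, StepDistribution2D
from .geometry import Disk, Interval, reflect_fold_1d

__all__ = ["Trajectory", "EnsembleResult", "simulate", "steps_of", "BOUNDARY_CONDITIONS"]

BOUNDARY_CONDITIONS = ("no_go", "stop_go", "reflecting")


@dataclass
class Trajectory:
    """Stopping locations of one run (N+1 points including the start)."""

    locations: np.ndarray  # (N+1,) in 1D or (N+1, 2) in 2D
    boundary_condition: str
    seed: int | None
    rejection_count: int = 0

    @property
    def steps(self) -> np.ndarray:
        return np.diff(self.locations, axis=0)


@dataclass
class EnsembleResult:
    """M runs sharing domain, step law and boundary condition.

    ``locations`` has shape (M, N+1) in 1D or (M, N+1, 2) in 2D.
    """

    locations: np.ndarray
    domain: object
    dist: object
    boundary_condition: str
    burn_in: int
    seed: int | None
    rejection_counts: np.ndarray = field(default=None)

    @property
    def n_runs(self) -> int:
        return self.locations.shape[0]

    @property
    def n_steps(self) -> int:
        return self.locations.shape[1] - 1

    @property
    def trajectories(self) -> list[Trajectory]:
        rej = (
            self.rejection_counts
            if self.rejection_counts is not None
            else np.zeros(self.n_runs, dtype=int)
        )
        return [
            Trajectory(self.locations[m], self.boundary_condition, self.seed, int(rej[m]))
            for m in range(self.n_runs)
        ]


def _dim_of(domain) -> int:
    return getattr(domain, "dim", 2)


def simulate(
    domain,
    dist,
    bc: str = "no_go",
    N: int = 1000,
    M: int = 1,
    burn_in: int | None = None,
    seed=None,
    max_attempts: int = 10**6,
) -> EnsembleResult:
    """Simulate M runs of N steps each under the given boundary condition.

    ``burn_in`` steps per run are tagged for exclusion from statistics
    (default: 1% of N).  ``max_attempts`` bounds the no-go rejection loop
    per walker and step; exceeding it signals a step law too
    short-ranged for some region of the geometry.
    """
    dim = _dim_of(domain)
    if bc not in BOUNDARY_CONDITIONS:
        raise ValueError(f"unknown boundary condition {bc!r}; choose from {BOUNDARY_CONDITIONS}")
    if dim == 2 and bc != "no_go":
        raise ValueError(f"boundary condition {bc!r} is supported in 1D only")
    if dim == 1 and not isinstance(dist, StepDistribution1D):
        raise TypeError("1D domain requires a StepDistribution1D")
    if dim == 2 and not isinstance(dist, StepDistribution2D):
        raise TypeError("2D domain requires a StepDistribution2D")
    if burn_in is None:
        burn_in = N // 100
    if not (0 <= burn_in < N):
        raise ValueError("require 0 <= burn_in < N")
    if M < 1:
        raise ValueError("M must be >= 1")

    rng = np.random.default_rng(seed)
    shape = (M, N + 1) if dim == 1 else (M, N + 1, 2)
    locations = np.empty(shape)
    rejections = np.zeros(M, dtype=np.int64)

    pos = domain.uniform_sample(M, rng)
    locations[:, 0] = pos

    for i in range(1, N + 1):
        prop = dist.sample(M, rng)
        if bc == "no_go":
            cand = pos + prop
            inside = domain.contains(cand)
            attempts = 1
            while not inside.all():
                if attempts >= max_attempts:
                    stuck = np.asarray(pos)[~inside][0]
                    raise RuntimeError(
                        f"no-go resampling exceeded {max_attempts} attempts at "
                        f"location {stuck!r}: step law cannot reach the domain "
                        "interior from there"
                    )
                bad = ~inside
                nbad = int(bad.sum())
                rejections[bad] += 1
                cand[bad] = np.asarray(pos)[bad] + dist.sample(nbad, rng)
                inside[bad] = domain.contains(cand[bad])
                attempts += 1
            pos = cand
        elif bc == "stop_go":
            # 1D: truncate at the first boundary crossing
            pos = np.clip(pos + prop, 0.0, domain.length)
        else:  # reflecting
            pos = reflect_fold_1d(pos + prop, domain.length)
        locations[:, i] = pos

    return EnsembleResult(
        locations=locations,
        domain=domain,
        dist=dist,
        boundary_condition=bc,
        burn_in=burn_in,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        rejection_counts=rejections,
    )


def steps_of(ensemble: EnsembleResult) -> np.ndarray:
    """Post-burn-in steps, shape (M, N - burn_in) or (M, N - burn_in, 2).

    Run boundaries are preserved (axis 0) so per-run statistics and
    ensemble envelopes can be formed downstream.
    """
    if ensemble.burn_in >= ensemble.n_steps:
        raise ValueError("burn_in must be smaller than the number of steps")
    steps = np.diff(ensemble.locations, axis=1)
    return steps[:, ensemble.burn_in :]


def post_burn_in_locations(ensemble: EnsembleResult) -> np.ndarray:
    """Stopping locations after burn-in, flattened over runs."""
    locs = ensemble.locations[:, ensemble.burn_in + 1 :]
    return locs.reshape(-1) if locs.ndim == 2 else locs.reshape(-1, 2)
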