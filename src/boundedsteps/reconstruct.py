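"""Estimation of empirical step densities and boundary-bias correction.

Under no-go boundaries the observed step density is the intrinsic one
multiplied by the domain's shaper function, so the intrinsic law can be
recovered bin-wise:

    f_i(l)  proportional to  f_t(l) / h(l),

and likewise for the step-magnitude forms with the angular-integrated
shaper.  The division is undefined where the shaper vanishes (steps at
or beyond the domain diameter cannot be observed) and unstable where it
is nearly zero; such bins are excluded and reported as missing, never as
zero.  Ensemble uncertainty is propagated by scaling the per-bin
standard deviation by the same 1/h factor, which makes the envelope
widen toward the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .shaper import ShaperFunction
from .simulator import EnsembleResult, steps_of

__all__ = [
    "DensityEstimate",
    "ReconstructionResult",
    "estimate_density",
    "reconstruct_intrinsic",
    "magnitude_bins",
    "signed_bins",
]


@dataclass
class DensityEstimate:
    """Binned density with an ensemble mean and standard-deviation envelope."""

    bin_edges: np.ndarray
    mean_density: np.ndarray
    std_density: np.ndarray | None
    n_runs: int
    normalised: bool = True

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mean_density = np.asarray(self.mean_density, dtype=float)
        if self.std_density is not None:
            self.std_density = np.asarray(self.std_density, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass
class ReconstructionResult:
    """Reconstructed intrinsic density with excluded-bin bookkeeping.

    Excluded bins (shaper below the floor or beyond the cutoff) hold NaN
    in ``mean_density``/``std_density`` and are listed in
    ``excluded_bins``.
    """

    estimate: DensityEstimate
    shaper_values: np.ndarray
    shaper_floor: float
    excluded_bins: np.ndarray  # integer indices

    @property
    def retained(self) -> np.ndarray:
        mask = np.ones(len(self.estimate.bin_centers), dtype=bool)
        mask[self.excluded_bins] = False
        return mask


def magnitude_bins(cutoff: float, n_bins: int = 60) -> np.ndarray:
    """Equal-width magnitude bins on [0, cutoff]."""
    return np.linspace(0.0, cutoff, n_bins + 1)


def signed_bins(cutoff: float, n_bins: int = 60) -> np.ndarray:
    """Symmetric equal-width bins on [-cutoff, cutoff]."""
    return np.linspace(-cutoff, cutoff, n_bins + 1)


def estimate_density(steps_by_run, bin_edges) -> DensityEstimate:
    """Per-run normalised histograms, summarised as mean +/- std per bin.

    ``steps_by_run`` is a sequence of 1D arrays (signed steps or
    magnitudes), one per run.  Data falling outside the bins are counted
    and reported via a warning, not silently dropped from the
    normalisation: each run's histogram is normalised to unit mass over
    the binned range.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least two entries")
    runs = [np.asarray(r, dtype=float).ravel() for r in steps_by_run]
    if not runs:
        raise ValueError("no runs supplied")
    if any(r.size == 0 for r in runs):
        raise ValueError("empty run supplied")
    outside = sum(int(np.count_nonzero((r < bin_edges[0]) | (r > bin_edges[-1]))) for r in runs)
    if outside:
        import warnings

        warnings.warn(
            f"{outside} steps fall outside the bin range "
            f"[{bin_edges[0]:g}, {bin_edges[-1]:g}] and are ignored",
            stacklevel=2,
        )
    hists = np.stack([np.histogram(r, bins=bin_edges, density=True)[0] for r in runs])
    mean = hists.mean(axis=0)
    std = hists.std(axis=0, ddof=0) if len(runs) > 1 else None
    return DensityEstimate(
        bin_edges=bin_edges,
        mean_density=mean,
        std_density=std,
        n_runs=len(runs),
        normalised=True,
    )


def estimate_step_density(ensemble: EnsembleResult, n_bins: int = 60) -> DensityEstimate:
    """Convenience: post-burn-in step histogram of an ensemble.

    1D ensembles are binned by signed step on [-diameter, diameter];
    2D ensembles by step magnitude on [0, diameter].
    """
    steps = steps_of(ensemble)
    diam = ensemble.domain.diameter
    if steps.ndim == 3:
        data = np.linalg.norm(steps, axis=2)
        edges = magnitude_bins(diam, n_bins)
    else:
        data = steps
        edges = signed_bins(diam, n_bins)
    return estimate_density(list(data), edges)


def reconstruct_intrinsic(
    ft_est: DensityEstimate,
    shaper: ShaperFunction,
    shaper_floor: float = 0.01,
    kind: str | None = None,
    renormalise: bool = False,
    n_angles: int | None = None,
) -> ReconstructionResult:
    """Invert the shaper multiplication to recover the intrinsic step law.

    Parameters
    ----------
    ft_est
        Binned empirical (transformed) step density.
    shaper
        Shaper function of the enclosing domain.
    shaper_floor
        Fraction of h(0) below which a bin is excluded: near the cutoff
        the 1/h^2 variance amplification swamps any signal.
    kind
        'signed' (1D steps, divide by h(l)) or 'magnitude' (step
        magnitudes, divide by the angular-integrated h~(l)); default by
        domain dimension.
    renormalise
        When true, rescale the retained bins to unit mass.  Off by
        default: the reconstruction is defined up to a constant and is
        usually compared against a known shape.
    """
    if not 0.0 < shaper_floor < 1.0:
        raise ValueError("shaper_floor must be a fraction in (0, 1)")
    if kind is None:
        kind = "signed" if shaper.domain.dim == 1 else "magnitude"
    centers = ft_est.bin_centers
    if kind == "signed":
        hvals = np.asarray(shaper.vector(centers), dtype=float)
        h0 = shaper.h0
    elif kind == "magnitude":
        if np.any(centers < 0):
            raise ValueError("magnitude reconstruction requires nonnegative bins")
        hvals = np.asarray(shaper.magnitude(centers, n_angles), dtype=float)
        h0 = float(shaper.magnitude(np.array([0.0]), n_angles)[0])
    else:
        raise ValueError("kind must be 'signed' or 'magnitude'")

    cut = shaper.cutoff
    excluded = (hvals < shaper_floor * h0) | (np.abs(centers) >= cut)
    if excluded.all():
        raise ValueError("all bins excluded: shaper floor too high or bins beyond the cutoff")

    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(excluded, np.nan, ft_est.mean_density / hvals)
        std = (
            np.where(excluded, np.nan, ft_est.std_density / hvals)
            if ft_est.std_density is not None
            else None
        )
    if renormalise:
        keep = ~excluded
        mass = float(np.nansum(mean[keep] * ft_est.bin_widths[keep]))
        if mass <= 0:
            raise ValueError("retained bins carry no mass; cannot renormalise")
        mean = mean / mass
        if std is not None:
            std = std / mass

    est = DensityEstimate(
        bin_edges=ft_est.bin_edges,
        mean_density=mean,
        std_density=std,
        n_runs=ft_est.n_runs,
        normalised=renormalise,
    )
    return ReconstructionResult(
        estimate=est,
        shaper_values=hvals,
        shaper_floor=shaper_floor,
        excluded_bins=np.flatnonzero(excluded),
    )
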