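"""Ensemble simulation under the three boundary conditions."""

import numpy as np
import pytest
from scipy import stats

import boundedsteps as bs
from boundedsteps.simulator import post_burn_in_locations


@pytest.mark.parametrize("bc", ["no_go", "stop_go", "reflecting"])
def test_1d_walker_never_leaves_domain(unit_interval, parabolic1d, bc):
    ens = bs.simulate(unit_interval, parabolic1d, bc=bc, N=500, M=5, burn_in=10, seed=1)
    assert np.all(unit_interval.contains(ens.locations))
    assert ens.boundary_condition == bc


def test_2d_walker_never_leaves_domain(square_ensemble, square):
    pts = square_ensemble.locations.reshape(-1, 2)
    assert np.all(square.contains(pts))


def test_same_seed_reproduces_ensemble(unit_interval, parabolic1d):
    a = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=200, M=3, burn_in=5, seed=9)
    b = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=200, M=3, burn_in=5, seed=9)
    assert np.array_equal(a.locations, b.locations)
    c = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=200, M=3, burn_in=5, seed=10)
    assert not np.array_equal(a.locations, c.locations)


def test_steps_of_counts_and_burn_in(unit_interval, parabolic1d):
    ens = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=10, M=2, burn_in=3, seed=2)
    steps = bs.steps_of(ens)
    assert steps.shape == (2, 7)  # (10 - 3) per run
    ens0 = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=10, M=2, burn_in=0, seed=2)
    assert bs.steps_of(ens0).shape == (2, 10)
    with pytest.raises(ValueError):
        bs.simulate(unit_interval, parabolic1d, bc="no_go", N=10, M=2, burn_in=10, seed=2)


def test_steps_are_successive_differences(square_ensemble):
    steps = bs.steps_of(square_ensemble)
    locs = square_ensemble.locations
    manual = np.diff(locs, axis=1)[:, square_ensemble.burn_in :]
    assert np.array_equal(steps, manual)


def test_unsupported_bc_dimension_pairs(square, parabolic2d, unit_interval, parabolic1d):
    with pytest.raises(ValueError, match="1D only"):
        bs.simulate(square, parabolic2d, bc="reflecting", N=10, M=1)
    with pytest.raises(ValueError, match="1D only"):
        bs.simulate(square, parabolic2d, bc="stop_go", N=10, M=1)
    with pytest.raises(ValueError, match="unknown boundary"):
        bs.simulate(unit_interval, parabolic1d, bc="bounce", N=10, M=1)
    with pytest.raises(TypeError):
        bs.simulate(square, parabolic1d, bc="no_go", N=10, M=1)


def test_nogo_resampling_guard_names_stuck_location(unit_interval):
    # every step has magnitude >= 2 > domain length: no proposal can land inside
    too_long = bs.Tabulated1D(np.linspace(2.0, 2.1, 20), np.ones(20))
    with pytest.raises(RuntimeError, match="attempts"):
        bs.simulate(unit_interval, too_long, bc="no_go", N=5, M=2, burn_in=0, seed=0, max_attempts=50)


def test_nogo_variance_reduction(unit_interval, parabolic1d):
    ens = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=4000, M=20, burn_in=100, seed=3)
    emp = float((bs.steps_of(ens) ** 2).mean())
    assert emp < parabolic1d.variance()  # a^2 / 5


def test_reflecting_stationary_locations_uniform(unit_interval, parabolic1d):
    ens = bs.simulate(unit_interval, parabolic1d, bc="reflecting", N=5100, M=20, burn_in=100, seed=4)
    locs = post_burn_in_locations(ens)
    assert locs.size == 100_000
    cnt, _ = np.histogram(locs, bins=20, range=(0, 1))
    chi2 = float(((cnt - cnt.mean()) ** 2 / cnt.mean()).sum())
    assert chi2 < stats.chi2.ppf(0.99, 19)


def test_nogo_stationary_locations_match_acceptance_mass(unit_interval, parabolic1d):
    """Stopping-location histogram follows g proportional to N(x)."""
    ens = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=5100, M=20, burn_in=100, seed=5)
    locs = post_burn_in_locations(ens)
    g = bs.stopping_density_nogo(unit_interval, parabolic1d, grid_n=2001)
    edges = np.linspace(0.0, 1.0, 21)
    fine = np.linspace(0.0, 1.0, 4001)
    gv = g(fine)
    probs = np.array(
        [
            np.trapezoid(gv[(fine >= lo) & (fine <= hi)], fine[(fine >= lo) & (fine <= hi)])
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
    )
    probs /= probs.sum()
    cnt, _ = np.histogram(locs, bins=edges)
    expected = probs * locs.size
    chi2 = float(((cnt - expected) ** 2 / expected).sum())
    assert chi2 < stats.chi2.ppf(0.99, 20 - 1)


def test_disk_stationary_radii_match_closed_form(disk):
    dist = bs.Gaussian2D(0.5)
    ens = bs.simulate(disk, dist, bc="no_go", N=2100, M=25, burn_in=100, seed=6)
    radii = np.linalg.norm(post_burn_in_locations(ens), axis=1)
    g = bs.stopping_density_nogo(disk, dist, grid_n=201)
    edges = np.linspace(0.0, 1.0, 16)
    centers = 0.5 * (edges[:-1] + edges[1:])
    pred = g(centers) * 2.0 * np.pi * centers  # radial density
    pred /= (pred * np.diff(edges)).sum()
    hist, _ = np.histogram(radii, bins=edges, density=True)
    n = radii.size
    p = pred * np.diff(edges)
    se = np.sqrt(p * (1 - p) / n) / np.diff(edges)
    assert np.mean(np.abs(hist - pred) <= 4.0 * se + 1e-12) >= 0.9


def test_nogo_step_histogram_matches_shaper_prediction(square_ensemble, square, parabolic2d):
    """Post-burn-in magnitude histogram matches f_i(l,0) * l * h~(l)."""
    est = bs.estimate_step_density(square_ensemble, n_bins=40)
    ft = bs.transformed_pdf_nogo_magnitude(parabolic2d, bs.shaper_for(square))
    pred = ft.pdf(est.bin_centers)
    within = np.abs(est.mean_density - pred) <= 3.0 * est.std_density + 1e-12
    assert within.mean() >= 0.95


def test_time_average_matches_ensemble_average(unit_interval, parabolic1d):
    """Ergodicity: one long run and many short runs agree on step moments."""
    long = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=60_000, M=1, burn_in=500, seed=7)
    many = bs.simulate(unit_interval, parabolic1d, bc="no_go", N=3000, M=20, burn_in=100, seed=8)
    t_avg = float(np.abs(bs.steps_of(long)).mean())
    per_run = np.abs(bs.steps_of(many)).mean(axis=1)
    e_avg = float(per_run.mean())
    se = float(per_run.std(ddof=1) / np.sqrt(per_run.size))
    assert abs(t_avg - e_avg) < 4.0 * se


def test_trajectory_records(square_ensemble):
    trajs = square_ensemble.trajectories
    assert len(trajs) == square_ensemble.n_runs
    t = trajs[0]
    assert t.steps.shape == (square_ensemble.n_steps, 2)
    assert t.boundary_condition == "no_go"
    assert t.rejection_count >= 0
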