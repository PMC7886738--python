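"""Stationary densities, Fredholm solver, transformed step densities."""

import numpy as np
import pytest
from scipy import integrate

import boundedsteps as bs
from boundedsteps.densities import gamma_circle, normalisation_N, transition_matrix_1d

FAMILIES_1D = [bs.Parabolic1D(0.75), bs.Gaussian1D(0.5), bs.Uniform1D(0.8)]


def test_acceptance_mass_uniform_window():
    """Uniform f_i on [-1, 1]: the window [-x, 1-x] always holds half the mass."""
    dom = bs.Interval(1.0)
    dist = bs.Uniform1D(1.0)
    for x in (0.0, 0.25, 0.5, 0.9, 1.0):
        assert normalisation_N(dom, dist, x) == pytest.approx(0.5, abs=1e-12)


def test_acceptance_mass_symmetry_and_saturation(unit_interval, parabolic1d):
    xs = np.array([0.1, 0.3, 0.45])
    np.testing.assert_allclose(
        normalisation_N(unit_interval, parabolic1d, xs),
        normalisation_N(unit_interval, parabolic1d, 1.0 - xs),
        atol=1e-12,
    )
    # short-range steps from the centre always land inside
    short = bs.Uniform1D(0.25)
    assert normalisation_N(unit_interval, short, 0.5) == pytest.approx(1.0, abs=1e-12)


def test_gamma_circle_spot_value():
    assert gamma_circle(1.0, 1.0) == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_nogo_stopping_density_symmetric_normalised(unit_interval, parabolic1d):
    g = bs.stopping_density_nogo(unit_interval, parabolic1d, grid_n=201)
    assert g.integral() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(g.values, g.values[::-1], atol=1e-10)
    assert np.all(g.values >= 0)


def test_disk_stopping_density_normalised(disk):
    g = bs.stopping_density_nogo(disk, bs.Gaussian2D(0.5), grid_n=201)
    assert g.integral() == pytest.approx(1.0, abs=1e-6)


def test_disk_fredholm_matches_closed_form(disk):
    dist = bs.Gaussian2D(0.5)
    sol = bs.fredholm_solve(disk, dist, bc="no_go", grid_n=101)
    g = bs.stopping_density_nogo(disk, dist, grid_n=101)
    assert np.max(np.abs(sol.values - g.values)) < 1e-2 * g.values.max()


@pytest.mark.parametrize("dist", FAMILIES_1D, ids=lambda d: d.family)
def test_fredholm_nogo_confirms_acceptance_mass_ansatz(unit_interval, dist):
    sol = bs.fredholm_solve(unit_interval, dist, bc="no_go", grid_n=201)
    g = bs.stopping_density_nogo(unit_interval, dist, grid_n=201)
    assert np.max(np.abs(sol.values - g.values)) < 1e-3
    assert sol.residual < 1e-8


@pytest.mark.parametrize("dist", FAMILIES_1D, ids=lambda d: d.family)
def test_fredholm_reflecting_stationary_is_uniform(unit_interval, dist):
    sol = bs.fredholm_solve(unit_interval, dist, bc="reflecting", grid_n=201)
    assert np.max(np.abs(sol.values - 1.0)) < 1e-3


def test_discrete_transition_conserves_probability(unit_interval, parabolic1d):
    """Outgoing mass per source node is exactly one after discretisation."""
    grid = np.linspace(0.0, 1.0, 201)
    for bc in ("no_go", "reflecting", "stop_go"):
        T = transition_matrix_1d(unit_interval, parabolic1d, bc, grid)
        T = T / T.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(T.sum(axis=0), 1.0, atol=1e-10)


def test_stopgo_fredholm_runs(unit_interval, parabolic1d):
    sol = bs.fredholm_solve(unit_interval, parabolic1d, bc="stop_go", grid_n=201)
    assert sol.integral() == pytest.approx(1.0, abs=1e-6)
    # boundary accumulation: the stop-go chain piles mass at the walls
    assert sol.values[0] > sol.values[len(sol.values) // 2]


def test_transformed_nogo_uniform_kernel_is_triangular(unit_interval):
    ft = bs.transformed_pdf_nogo(bs.Uniform1D(1.0), bs.shaper_for(unit_interval))
    ell = np.linspace(-0.99, 0.99, 41)
    np.testing.assert_allclose(ft.pdf(ell), 1.0 - np.abs(ell), atol=1e-9)
    assert ft.pdf(1.2) == 0.0


@pytest.mark.parametrize("dist", FAMILIES_1D, ids=lambda d: d.family)
def test_transformed_nogo_reduces_variance_1d(unit_interval, dist):
    ft = bs.transformed_pdf_nogo(dist, bs.shaper_for(unit_interval))
    assert ft.variance() < dist.variance()


def test_transformed_densities_normalised(unit_interval, parabolic1d, square, parabolic2d):
    for f, (lo, hi) in [
        (bs.transformed_pdf_nogo(parabolic1d, bs.shaper_for(unit_interval)), (-1, 1)),
        (bs.transformed_pdf_stopgo_1d(parabolic1d), (-1, 1)),
        (bs.transformed_pdf_reflecting_1d(parabolic1d), (-1, 1)),
        (bs.transformed_pdf_nogo_magnitude(parabolic2d, bs.shaper_for(square)), (0, np.sqrt(2))),
    ]:
        mass, _ = integrate.quad(f.pdf, lo, hi, limit=400)
        assert mass == pytest.approx(1.0, abs=1e-6)


def test_transformed_stopgo_matches_first_step_simulation(unit_interval, parabolic1d):
    """Uniform start, single stop-go step: histogram vs the analytic density."""
    ens = bs.simulate(unit_interval, parabolic1d, bc="stop_go", N=1, M=50_000, burn_in=0, seed=3)
    s1 = bs.steps_of(ens).ravel()
    ft = bs.transformed_pdf_stopgo_1d(parabolic1d)
    # symmetry in the analytic form
    ell = np.linspace(0.0, 0.99, 21)
    np.testing.assert_allclose(ft.pdf(ell), ft.pdf(-ell), atol=1e-12)
    # tail-integral term vanishes beyond the support: f_t reduces to f_i h = 0
    assert ft.pdf(0.9) == pytest.approx(0.0, abs=1e-12)
    edges = np.linspace(-1, 1, 41)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist, _ = np.histogram(s1, bins=edges, density=True)
    pred = ft.pdf(centers)
    p = pred * np.diff(edges)
    se = np.sqrt(p * (1 - p) / s1.size) / np.diff(edges)
    within = np.abs(hist - pred) <= 3.0 * se + 1e-12
    assert within.mean() >= 0.95


def test_transformed_reflecting_matches_simulation(unit_interval, parabolic1d):
    """Image-sum density vs the folding simulator (independent mechanisms)."""
    ens = bs.simulate(unit_interval, parabolic1d, bc="reflecting", N=5100, M=20, burn_in=100, seed=4)
    steps = bs.steps_of(ens).ravel()
    ft = bs.transformed_pdf_reflecting_1d(parabolic1d)
    edges = np.linspace(-1, 1, 41)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist, _ = np.histogram(steps, bins=edges, density=True)
    pred = ft.pdf(centers)
    p = np.maximum(pred * np.diff(edges), 1e-12)
    se = np.sqrt(p * (1 - p) / steps.size) / np.diff(edges)
    within = np.abs(hist - pred) <= 4.0 * se + 1e-12
    assert within.mean() >= 0.95


def test_reflecting_single_image_suffices_for_short_support(parabolic1d):
    """Support within (-2, 2): higher-order image terms contribute nothing."""
    one = bs.transformed_pdf_reflecting_1d(parabolic1d, n_images=1)
    many = bs.transformed_pdf_reflecting_1d(parabolic1d, n_images=6)
    ell = np.linspace(-0.99, 0.99, 101)
    np.testing.assert_allclose(one.pdf(ell), many.pdf(ell), atol=1e-12)


def test_polygon_acceptance_mass(square, parabolic2d):
    """Centre of the unit square accepts more proposals than a corner."""
    centre = normalisation_N(square, parabolic2d, np.array([0.5, 0.5]))
    corner = normalisation_N(square, parabolic2d, np.array([0.02, 0.02]))
    assert 0 < corner < centre <= 1.0 + 1e-9
    # consistency with the disk path: square centre vs quadrature
    def integrand(y, x):
        return parabolic2d.pdf(x - 0.5, y - 0.5)

    ref, _ = integrate.dblquad(integrand, 0, 1, 0, 1, epsabs=1e-10)
    assert centre == pytest.approx(ref, abs=2e-3)
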