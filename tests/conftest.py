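import numpy as np
import pytest

import boundedsteps as bs

try:
    from hypothesis import settings

    settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def unit_interval():
    return bs.Interval(1.0)


@pytest.fixture(scope="session")
def square():
    return bs.unit_square()


@pytest.fixture(scope="session")
def disk():
    return bs.Disk(1.0)


@pytest.fixture(scope="session")
def parabolic1d():
    return bs.Parabolic1D(0.75)


@pytest.fixture(scope="session")
def parabolic2d():
    return bs.Parabolic2D(0.75)


@pytest.fixture(scope="session")
def square_ensemble(square, parabolic2d):
    """Moderate-size no-go ensemble on the unit square, shared across tests."""
    return bs.simulate(square, parabolic2d, bc="no_go", N=3000, M=60, burn_in=60, seed=101)


def random_convex_polygon(rng: np.random.Generator, n_points: int = 10) -> bs.ConvexPolygon:
    """Convex hull of random points in the unit square (CCW order)."""
    from scipy.spatial import ConvexHull

    pts = rng.random((n_points, 2))
    hull = ConvexHull(pts)
    return bs.ConvexPolygon(pts[hull.vertices])
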