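import numpy as np
import pytest

import sfekin as sk


@pytest.fixture(scope="session")
def table1():
    return sk.load_fixture("table1")


@pytest.fixture(scope="session")
def table3():
    return sk.load_fixture("table3")


@pytest.fixture(scope="session")
def selectivity_fit(table3):
    """The Box-Behnken selectivity surface refit used across tests."""
    return sk.ResponseSurfaceModel(table3, "selectivity").fit()


@pytest.fixture(scope="session")
def sovova_example():
    """A parameter set in the regime of a milled-flower extraction."""
    return sk.SovovaParameters(x0=0.06, xk=0.035, yr=0.54, Z=0.05, W=0.08)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260901)


def fd_sphere_fraction(fo_grid, n_shells=200):
    """Finite-difference oracle for diffusion out of a sphere.

    Solves the radial diffusion problem via the substitution v = u * xi
    (which turns the spherical Laplacian into a plain 1-D one) on
    ``n_shells`` interior nodes with a stiff integrator, and returns the
    cumulative extracted fraction 1 - 3 * int(v * xi dxi) on the Fourier-
    number grid.  Independent of the series implementation.
    """
    from scipy.integrate import solve_ivp

    fo_grid = np.asarray(fo_grid, dtype=float)
    m = n_shells
    h = 1.0 / m
    xi = np.linspace(h, 1.0 - h, m - 1)
    v0 = xi.copy()  # u(xi, 0) = 1, v = u * xi

    main = np.full(m - 1, -2.0) / h**2
    off = np.full(m - 2, 1.0) / h**2

    def rhs(_t, v):
        lap = main * v
        lap[:-1] += off * v[1:]
        lap[1:] += off * v[:-1]
        return lap

    import scipy.sparse as sp

    J = sp.diags([off, main, off], [-1, 0, 1], format="csc")
    sol = solve_ivp(
        rhs, (0.0, fo_grid[-1]), v0, method="BDF", t_eval=fo_grid,
        jac=lambda t, v: J, rtol=1e-9, atol=1e-12,
    )
    assert sol.success
    out = np.empty(fo_grid.size)
    grid = np.concatenate([[0.0], xi, [1.0]])
    for j in range(fo_grid.size):
        v = np.concatenate([[0.0], sol.y[:, j], [0.0]])
        out[j] = 1.0 - 3.0 * np.trapezoid(v * grid, grid)
    return out
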