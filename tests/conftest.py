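import numpy as np
import pytest

import pmfkit as pk


@pytest.fixture(scope="session")
def double_well():
    """Symmetric double well with an exact 13.8 kcal/mol barrier."""
    return pk.make_surface("double_well_2d", barrier=13.8)


@pytest.fixture(scope="session")
def muller_brown():
    return pk.make_surface("muller_brown_scaled")


@pytest.fixture(scope="session")
def mb_oracle(muller_brown):
    """Brute-force stationary points of the scaled Muller-Brown surface.

    Exhaustive gradient-norm minimization on a dense analytic grid,
    independent of the grid-FES saddle finder it validates.  Saddles are the
    gradient-norm minima whose analytic Hessian (by tight finite differences
    on the analytic gradient) is indefinite.
    """
    from scipy.ndimage import minimum_filter

    mb = muller_brown
    x = np.linspace(*mb.domain[0], 2001)
    y = np.linspace(*mb.domain[1], 2001)
    g = mb.gradient(x[:, None], y[None, :])
    gn = np.hypot(g[..., 0], g[..., 1])
    local = gn <= minimum_filter(gn, size=3)
    pts = {"minima": [], "saddles": []}
    h = 1e-6
    for i, j in np.argwhere(local & (gn < 0.1)):
        xi, yj = x[i], y[j]
        fxx = (mb.gradient(xi + h, yj)[0] - mb.gradient(xi - h, yj)[0]) / (2 * h)
        fyy = (mb.gradient(xi, yj + h)[1] - mb.gradient(xi, yj - h)[1]) / (2 * h)
        fxy = (mb.gradient(xi, yj + h)[0] - mb.gradient(xi, yj - h)[0]) / (2 * h)
        eig = np.linalg.eigvalsh([[fxx, fxy], [fxy, fyy]])
        kind = "saddles" if eig[0] < 0 < eig[1] else "minima"
        e = float(mb.energy(xi, yj))
        if all(abs(xi - p[0]) > 0.01 or abs(yj - p[1]) > 0.01 for p in pts[kind]):
            pts[kind].append((float(xi), float(yj), e))
    return pts


def recover_harmonic_curvature(seed: int, k_true: float = 2.0) -> tuple[float, float]:
    """Umbrella-sample a harmonic well, WHAM it, and fit back the curvature.

    The quadratic fit is restricted to the window-covered design region,
    where every bin is densely sampled; bins reached only by exponential
    tails carry large free-energy noise and no design coverage.
    """
    surf = pk.make_surface("harmonic_well", curvature=k_true, half_width=3.0)
    windows = pk.gen_window_grid((-1.2, 1.2), (-1.2, 1.2), 9, 9, 10.0, 10.0)
    cfg = pk.SamplerConfig(n_relax_steps=2000, n_production_steps=20_000, seed=seed)
    series = pk.sample_windows(surf, windows, cfg)
    grid = pk.GridSpec((-1.8, 1.8), (-1.8, 1.8), 48, 48)
    fes = pk.solve_wham(windows, series, grid, temperature=300.0)
    x = np.broadcast_to(grid.centers1[:, None], fes.values.shape)
    y = np.broadcast_to(grid.centers2[None, :], fes.values.shape)
    ok = ~fes.mask & (np.abs(x) <= 1.2) & (np.abs(y) <= 1.2)
    xs, ys = x[ok], y[ok]
    a = np.column_stack([np.ones_like(xs), xs, ys, xs**2, xs * ys, ys**2])
    c, *_ = np.linalg.lstsq(a, fes.values[ok], rcond=None)
    return float(2 * c[3]), float(2 * c[5])


@pytest.fixture(scope="session")
def sampled_double_well(double_well):
    """A reduced umbrella run on the double well, shared across WHAM tests.

    20 x 20 windows, k = 50 kcal/mol/A^2, 4000 relaxation + 6000 production
    steps per window: enough depth to resolve the 13.8 kcal/mol barrier to a
    few tenths while keeping the suite quick.
    """
    windows = pk.gen_window_grid((-2.0, 2.0), (1.0, 3.0), 20, 20, 50.0, 50.0)
    config = pk.SamplerConfig(n_relax_steps=4000, n_production_steps=6000, seed=11)
    series = pk.sample_windows(double_well, windows, config)
    return windows, series
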