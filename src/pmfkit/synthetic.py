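"""Synthetic inputs for the free-energy pipeline.

Everything downstream (WHAM, surface analysis, corrections, decomposition)
consumes plain data: window definitions, biased coordinate time series, and
point-charge systems.  This module generates all of them from analytically
known ground truths, so the pipeline is testable end to end with no
molecular-dynamics or quantum-chemistry engine:

* analytic 2D free-energy surfaces (harmonic well, double well with an exact
  barrier, a scaled Muller-Brown-type surface) with closed-form gradients;
* a Metropolis random walker in the two collective coordinates that samples
  the Boltzmann distribution of surface-plus-harmonic-bias, standing in for
  restrained QM/MM molecular dynamics — WHAM consumes only the biased
  coordinate distributions, which the walker reproduces exactly in the long
  run;
* toy multi-residue charge systems whose per-residue interaction energies are
  known from direct summation.

Default sampling mirrors the umbrella design used for the enzyme studies this
package targets: 40 x 40 windows over [-2, 2] A x [1, 3] A, force constant
50 kcal/mol/A^2 on each coordinate, 300 K, equal relaxation and production
phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import KB
from .decomposition import ChargeSystem
from .wham import TimeSeries, Window

__all__ = [
    "AnalyticSurface",
    "SamplerConfig",
    "make_surface",
    "gen_window_grid",
    "sample_biased",
    "sample_windows",
    "make_toy_complex",
    "fes_from_surface",
]


@dataclass
class AnalyticSurface:
    """A 2D energy surface with analytic energy and gradient.

    Energies are in kcal/mol, coordinates in A.  The global minimum is zero
    by construction (an additive offset is fixed when the surface is built).
    ``metadata`` carries exact derived quantities (well positions, saddle
    location/energy, barrier height) where the family admits them.
    """

    name: str
    params: dict
    domain: tuple[tuple[float, float], tuple[float, float]]
    _energy: callable = field(repr=False)
    _gradient: callable = field(repr=False)
    metadata: dict = field(default_factory=dict)

    def energy(self, xi1, xi2):
        return self._energy(np.asarray(xi1, dtype=float), np.asarray(xi2, dtype=float))

    def gradient(self, xi1, xi2):
        return self._gradient(np.asarray(xi1, dtype=float), np.asarray(xi2, dtype=float))

    def contains(self, xi1, xi2):
        (l1, h1), (l2, h2) = self.domain
        return (xi1 >= l1) & (xi1 <= h1) & (xi2 >= l2) & (xi2 <= h2)


def _harmonic_well(params: dict) -> AnalyticSurface:
    k1 = float(params.get("curvature1", params.get("curvature", 2.0)))
    k2 = float(params.get("curvature2", params.get("curvature", 2.0)))
    cx, cy = params.get("center", (0.0, 0.0))
    if k1 <= 0 or k2 <= 0:
        raise ValueError("harmonic_well curvatures must be positive")
    half = params.get("half_width", 3.0)
    domain = ((cx - half, cx + half), (cy - half, cy + half))

    def energy(x, y):
        return 0.5 * k1 * (x - cx) ** 2 + 0.5 * k2 * (y - cy) ** 2

    def gradient(x, y):
        return np.stack([k1 * (x - cx), k2 * (y - cy)], axis=-1)

    return AnalyticSurface(
        name="harmonic_well",
        params={"curvature1": k1, "curvature2": k2, "center": (cx, cy)},
        domain=domain,
        _energy=energy,
        _gradient=gradient,
        metadata={"minimum": (cx, cy)},
    )


def _double_well_2d(params: dict) -> AnalyticSurface:
    """Quartic double well along axis 1, harmonic along axis 2.

    E(x, y) = h ((x^2 - a^2)^2 / a^4) + tilt * x + ky/2 (y - y0)^2 - E_min.

    With tilt = 0 the wells sit at x = +-a with energy 0 and the saddle at
    (0, y0) with energy exactly ``barrier`` = h.  A nonzero tilt deepens one
    well; stationary points then come from the cubic derivative and the
    metadata barrier is saddle energy minus the deeper-well energy.
    """
    h = float(params.get("barrier", 10.0))
    a = float(params.get("well_sep", 1.0))
    ky = float(params.get("y_curvature", 10.0))
    y0 = float(params.get("y_center", 2.0))
    tilt = float(params.get("tilt", 0.0))
    if h <= 0 or a <= 0 or ky <= 0:
        raise ValueError("double_well_2d requires barrier, well_sep, y_curvature > 0")

    # stationary x of the 1D part: 4h/a^4 x^3 - 4h/a^2 x + tilt = 0
    roots = np.roots([4 * h / a**4, 0.0, -4 * h / a**2, tilt])
    xs = np.sort(roots[np.abs(roots.imag) < 1e-10].real)
    quartic = lambda x: h * (x**2 - a**2) ** 2 / a**4 + tilt * x
    if len(xs) != 3:
        raise ValueError("tilt too large: the double well degenerates to one well")
    e_stat = quartic(xs)
    e_min = min(e_stat[0], e_stat[2])
    barrier = float(e_stat[1] - e_min)
    wells = [(float(xs[0]), y0), (float(xs[2]), y0)]

    def energy(x, y):
        return quartic(x) - e_min + 0.5 * ky * (y - y0) ** 2

    def gradient(x, y):
        gx = 4 * h / a**4 * x**3 - 4 * h / a**2 * x + tilt
        return np.stack([gx, ky * (y - y0)], axis=-1)

    dom1 = params.get("domain1", (-2.0, 2.0))
    dom2 = params.get("domain2", (y0 - 1.0, y0 + 1.0))
    return AnalyticSurface(
        name="double_well_2d",
        params={"barrier": h, "well_sep": a, "y_curvature": ky, "y_center": y0, "tilt": tilt},
        domain=(tuple(dom1), tuple(dom2)),
        _energy=energy,
        _gradient=gradient,
        metadata={
            "barrier": barrier,
            "saddle": (float(xs[1]), y0),
            "saddle_energy": float(e_stat[1] - e_min),
            "wells": wells,
            "well_energies": [float(e_stat[0] - e_min), float(e_stat[2] - e_min)],
        },
    )


# Muller-Brown parameter set (energies later multiplied by `scale`)
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def _muller_brown_scaled(params: dict) -> AnalyticSurface:
    """Muller-Brown surface scaled into the kcal/mol range, shifted to min 0.

    The classic three-minima/two-saddles benchmark for transition-state
    finders.  ``scale`` (default 0.05) brings its ~147-unit depth down to
    ~7 kcal/mol.  The global-minimum offset is located numerically at build
    time from the well-known basin near (-0.558, 1.442).
    """
    scale = float(params.get("scale", 0.05))
    if scale <= 0:
        raise ValueError("scale must be positive")

    def raw(x, y):
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        dx = x - _MB_x0
        dy = y - _MB_y0
        return (_MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)).sum(axis=-1)

    res = minimize(lambda p: raw(p[0], p[1]), x0=np.array([-0.558, 1.442]), method="BFGS")
    offset = float(res.fun)
    xmin = tuple(float(v) for v in res.x)

    def energy(x, y):
        return scale * (raw(x, y) - offset)

    def gradient(x, y):
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        dx = x - _MB_x0
        dy = y - _MB_y0
        e = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
        gx = (e * (2 * _MB_a * dx + _MB_b * dy)).sum(axis=-1)
        gy = (e * (_MB_b * dx + 2 * _MB_c * dy)).sum(axis=-1)
        return scale * np.stack([gx, gy], axis=-1)

    return AnalyticSurface(
        name="muller_brown_scaled",
        params={"scale": scale},
        domain=((-1.7, 1.3), (-0.4, 2.1)),
        _energy=energy,
        _gradient=gradient,
        metadata={"scale": scale, "global_minimum": xmin, "raw_min_energy": offset},
    )


_FAMILIES = {
    "harmonic_well": _harmonic_well,
    "double_well_2d": _double_well_2d,
    "muller_brown_scaled": _muller_brown_scaled,
}


def make_surface(name: str, **params) -> AnalyticSurface:
    """Build a named analytic surface family with the given parameters."""
    try:
        builder = _FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown surface family {name!r}; choose from {sorted(_FAMILIES)}") from None
    surf = builder(params)
    (l1, h1), (l2, h2) = surf.domain
    probe = surf.energy(np.linspace(l1, h1, 33)[:, None], np.linspace(l2, h2, 33)[None, :])
    if not np.isfinite(probe).all():
        raise ValueError(f"surface {name!r} is non-finite on its domain with params {params}")
    return surf


def gen_window_grid(
    range1: tuple[float, float],
    range2: tuple[float, float],
    n1: int,
    n2: int,
    k1: float,
    k2: float,
) -> list[Window]:
    """Evenly spaced umbrella window centers (endpoints included) over a rectangle.

    The default study design uses n1 = n2 = 40 over [-2, 2] A x [1, 3] A with
    k = 50 kcal/mol/A^2 on both coordinates, i.e. 1600 windows.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 windows per axis")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("force constants must be positive")
    if range1[1] <= range1[0] or range2[1] <= range2[0]:
        raise ValueError("degenerate window range")
    c1 = np.linspace(*range1, n1)
    c2 = np.linspace(*range2, n2)
    return [
        Window(center=(float(a), float(b)), force_constants=(k1, k2), label=f"w{i:04d}")
        for i, (a, b) in enumerate((a, b) for a in c1 for b in c2)
    ]


@dataclass(frozen=True)
class SamplerConfig:
    """Metropolis walker settings.

    The relaxation/production split mirrors the equal-length equilibration and
    production phases of the umbrella protocol this sampler stands in for.
    ``step_size`` is the proposal standard deviation (A); 0.05 A keeps the
    acceptance rate in the 30-60% range under a 50 kcal/mol/A^2 bias at 300 K.
    """

    n_relax_steps: int = 20_000
    n_production_steps: int = 20_000
    step_size: float = 0.05
    temperature: float = 300.0
    seed: int = 2024

    def __post_init__(self) -> None:
        if self.n_relax_steps < 0 or self.n_production_steps <= 0:
            raise ValueError("step counts must be positive")
        if self.step_size <= 0 or self.temperature <= 0:
            raise ValueError("step_size and temperature must be positive")


def sample_windows(
    surface: AnalyticSurface,
    windows: list[Window],
    config: SamplerConfig,
) -> list[TimeSeries]:
    """Metropolis-sample every window in one vectorized chain array.

    All windows advance in lockstep: each step draws one Gaussian proposal
    and one uniform per window from a single seeded generator, so the full
    batch is bit-reproducible from ``config.seed``.  Walkers start at their
    window centers; proposals leaving the surface domain are rejected
    (symmetric proposals keep detailed balance).  Relaxation samples are
    discarded.  A window that accepts no move over the entire run raises,
    rather than returning a frozen series.
    """
    if not windows:
        return []
    centers = np.array([w.center for w in windows])            # (n, 2)
    ks = np.array([w.force_constants for w in windows])        # (n, 2)
    if not np.all(surface.contains(centers[:, 0], centers[:, 1])):
        bad = [w.label or i for i, w in enumerate(windows)
               if not surface.contains(*w.center)]
        raise ValueError(f"window centers outside surface domain: {bad}")

    beta = 1.0 / (KB * config.temperature)
    rng = np.random.default_rng(config.seed)
    n = len(windows)
    x = centers.copy()
    e = surface.energy(x[:, 0], x[:, 1]) + 0.5 * (ks * (x - centers) ** 2).sum(axis=1)
    accepted = np.zeros(n, dtype=np.int64)
    n_total = config.n_relax_steps + config.n_production_steps
    out1 = np.empty((config.n_production_steps, n))
    out2 = np.empty((config.n_production_steps, n))

    for step in range(n_total):
        prop = x + rng.normal(0.0, config.step_size, size=(n, 2))
        inside = surface.contains(prop[:, 0], prop[:, 1])
        e_prop = np.where(
            inside,
            surface.energy(prop[:, 0], prop[:, 1])
            + 0.5 * (ks * (prop - centers) ** 2).sum(axis=1),
            np.inf,
        )
        u = rng.random(n)
        acc = inside & (np.log(u) < -beta * (e_prop - e))
        x[acc] = prop[acc]
        e[acc] = e_prop[acc]
        accepted += acc
        i = step - config.n_relax_steps
        if i >= 0:
            out1[i] = x[:, 0]
            out2[i] = x[:, 1]

    frozen = np.nonzero(accepted == 0)[0]
    if len(frozen):
        labels = [windows[int(i)].label or int(i) for i in frozen]
        raise RuntimeError(
            f"zero Metropolis acceptance over {n_total} steps for windows {labels}; "
            "step size is pathological for this surface/bias"
        )
    return [
        TimeSeries(xi1=out1[:, i].copy(), xi2=out2[:, i].copy(), label=w.label)
        for i, w in enumerate(windows)
    ]


def sample_biased(
    surface: AnalyticSurface, window: Window, config: SamplerConfig
) -> TimeSeries:
    """Metropolis samples from Boltzmann(surface + harmonic window bias).

    Single-window convenience over :func:`sample_windows`; identical seed and
    config give a bit-identical series.
    """
    return sample_windows(surface, [window], config)[0]


def fes_from_surface(surface: AnalyticSurface, grid) -> "FES":
    """Evaluate an analytic surface on a histogram grid as an exact FES.

    Useful as sampling-free ground truth for the surface-analysis routines;
    every bin is unmasked and the minimum is renormalized to zero on the grid.
    """
    from .wham import FES

    vals = surface.energy(grid.centers1[:, None], grid.centers2[None, :])
    vals = vals - vals.min()
    return FES(
        values=vals,
        mask=np.zeros_like(vals, dtype=bool),
        grid=grid,
        temperature=300.0,
    )


def _brute_force_residue_energies(
    coords: np.ndarray,
    charges: np.ndarray,
    residue_of: np.ndarray,
    qm_mask: np.ndarray,
) -> dict[int, float]:
    """Ground-truth per-residue Coulomb energies by an explicit double loop.

    Deliberately naive (atom-by-atom python loops, no vectorization) so it is
    independent of the decomposition module it validates.
    """
    from .constants import COULOMB

    out: dict[int, float] = {}
    qm_idx = [i for i in range(len(charges)) if qm_mask[i]]
    for j in range(len(charges)):
        if qm_mask[j]:
            continue
        acc = out.setdefault(int(residue_of[j]), 0.0)
        for i in qm_idx:
            r = math.dist(coords[i], coords[j])
            acc += COULOMB * charges[i] * charges[j] / r
        out[int(residue_of[j])] = acc
    return out


def make_toy_complex(
    n_residues: int,
    n_qm_atoms: int,
    seed: int = 2024,
    min_separation: float = 1.0,
    zero_charges: bool = False,
) -> ChargeSystem:
    """Random toy protein-ligand charge system with known per-residue energies.

    A compact QM cluster (the "substrate") sits at the origin; ``n_residues``
    MM residues of 1-5 atoms each are scattered on shells 6-20 A away, with a
    minimum inter-atom separation enforced by rejection (bounded retries).
    Per-atom partial charges are drawn uniformly from [-0.6, 0.6] e.  The
    exact per-residue Coulomb energies, computed by direct double-loop
    summation, are attached under ``metadata['true_residue_energies']``
    (keyed by residue number) together with their total.
    """
    if n_residues < 1 or n_qm_atoms < 1:
        raise ValueError("need at least one residue and one QM atom")
    rng = np.random.default_rng(seed)

    coords: list[np.ndarray] = []

    def place(center: np.ndarray, spread: float) -> np.ndarray:
        for _ in range(2000):
            p = center + rng.uniform(-spread, spread, size=3)
            if all(np.linalg.norm(p - q) >= min_separation for q in coords):
                coords.append(p)
                return p
        raise RuntimeError("toy-complex geometry generation failed: cannot satisfy min separation")

    rows = {"charge": [], "resSeq": [], "qm": [], "resName": [], "chain": []}
    for _ in range(n_qm_atoms):
        place(np.zeros(3), spread=max(2.0, n_qm_atoms ** (1 / 3)))
        rows["charge"].append(rng.uniform(-0.6, 0.6))
        rows["resSeq"].append(0)
        rows["qm"].append(True)
        rows["resName"].append("LIG")
        rows["chain"].append("X")
    for r in range(1, n_residues + 1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = direction * rng.uniform(6.0, 20.0)
        for _ in range(int(rng.integers(1, 6))):
            place(center, spread=1.5)
            rows["charge"].append(rng.uniform(-0.6, 0.6))
            rows["resSeq"].append(r)
            rows["qm"].append(False)
            rows["resName"].append("RES")
            rows["chain"].append("A")

    n = len(coords)
    charge = np.zeros(n) if zero_charges else np.array(rows["charge"])
    resseq = np.array(rows["resSeq"])
    qm = np.array(rows["qm"])
    truth = _brute_force_residue_energies(np.array(coords), charge, resseq, qm)
    system = ChargeSystem(
        serial=np.arange(1, n + 1),
        coords=np.array(coords),
        charge=charge,
        chain=np.array(rows["chain"], dtype=object),
        resSeq=resseq,
        iCode=np.array([""] * n, dtype=object),
        resName=np.array(rows["resName"], dtype=object),
        qm_mask=qm,
        metadata={
            "true_residue_energies": truth,
            "true_total": float(sum(truth.values())),
            "seed": seed,
        },
    )
    return system
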