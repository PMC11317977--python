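"""2D weighted-histogram analysis (WHAM) for umbrella-sampling data.

Reconstructs a two-dimensional potential of mean force from biased window
samples by the standard self-consistent binned WHAM iteration: each window
``i`` with ``N_i`` samples and harmonic bias ``b_i`` contributes to the
unbiased bin probabilities

    p_l = M_l / sum_i N_i exp(beta (f_i - b_i(l)))
    f_i = -kT ln sum_l exp(-beta b_i(l)) p_l

where ``M_l`` is the total count in bin ``l`` and the bias is evaluated at
bin centers.  Iteration stops when the largest per-iteration change in any
window offset ``f_i`` drops below a tolerance; hitting the iteration cap is
an explicit non-converged status, never a silent success.  Probabilities are
converted to free energies at the run temperature, the minimum of the
unmasked grid is shifted to zero, and bins with zero total counts are masked.

Samples are weighted equally (no statistical-inefficiency correction) and a
single temperature is assumed throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import KB

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "TimeSeries",
    "GridSpec",
    "FES",
    "solve_wham",
    "overlap_report",
]


@dataclass(frozen=True)
class Window:
    """One umbrella restraint: a 2D center with per-axis force constants.

    A force constant of 0 means no bias along that axis (used for unbiased
    single-window reference runs); negative force constants are invalid.
    """

    center: tuple[float, float]
    force_constants: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.center) != 2 or len(self.force_constants) != 2:
            raise ValueError("Window is two-dimensional: need 2 centers and 2 force constants")
        if any(k < 0 for k in self.force_constants):
            raise ValueError(f"negative force constant in window {self.label!r}: {self.force_constants}")

    def bias(self, xi1, xi2):
        """Harmonic bias energy (kcal/mol) at coordinates (xi1, xi2)."""
        c1, c2 = self.center
        k1, k2 = self.force_constants
        return 0.5 * k1 * (np.asarray(xi1) - c1) ** 2 + 0.5 * k2 * (np.asarray(xi2) - c2) ** 2


@dataclass
class TimeSeries:
    """Ordered biased samples of the two reaction coordinates for one window."""

    xi1: np.ndarray
    xi2: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.xi1 = np.asarray(self.xi1, dtype=float)
        self.xi2 = np.asarray(self.xi2, dtype=float)
        if self.xi1.shape != self.xi2.shape or self.xi1.ndim != 1:
            raise ValueError("xi1 and xi2 must be 1D arrays of equal length")

    def __len__(self) -> int:
        return self.xi1.size


@dataclass(frozen=True)
class GridSpec:
    """Rectangular histogram grid: per-axis range (A) and bin counts."""

    range1: tuple[float, float]
    range2: tuple[float, float]
    bins1: int
    bins2: int

    def __post_init__(self) -> None:
        if self.bins1 < 2 or self.bins2 < 2:
            raise ValueError("need at least 2 bins per axis")
        if self.range1[1] <= self.range1[0] or self.range2[1] <= self.range2[0]:
            raise ValueError("degenerate grid range")

    @property
    def edges1(self) -> np.ndarray:
        return np.linspace(*self.range1, self.bins1 + 1)

    @property
    def edges2(self) -> np.ndarray:
        return np.linspace(*self.range2, self.bins2 + 1)

    @property
    def centers1(self) -> np.ndarray:
        e = self.edges1
        return 0.5 * (e[:-1] + e[1:])

    @property
    def centers2(self) -> np.ndarray:
        e = self.edges2
        return 0.5 * (e[:-1] + e[1:])

    @property
    def widths(self) -> tuple[float, float]:
        return (
            (self.range1[1] - self.range1[0]) / self.bins1,
            (self.range2[1] - self.range2[0]) / self.bins2,
        )


@dataclass
class FES:
    """Masked 2D free-energy grid in kcal/mol.

    ``values[i, j]`` is the free energy at ``(centers1[i], centers2[j])``;
    masked bins were never visited and are excluded from all downstream
    analysis.  The minimum over unmasked bins is zero after normalization.
    """

    values: np.ndarray          # (bins1, bins2), kcal/mol; NaN where masked
    mask: np.ndarray            # True where the bin is empty / invalid
    grid: GridSpec
    temperature: float
    window_offsets: np.ndarray = field(default_factory=lambda: np.zeros(0))
    iterations: int = 0
    converged: bool = True
    final_max_change: float = 0.0
    n_outside: int = 0
    convergence_history: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.grid.bins1, self.grid.bins2):
            raise ValueError("FES values shape does not match grid")
        if self.mask.shape != self.values.shape:
            raise ValueError("FES mask shape does not match values")

    @property
    def masked_values(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.mask)

    def normalized(self) -> "FES":
        """Return a copy with the unmasked minimum shifted to zero."""
        if self.mask.all():
            raise ValueError("cannot normalize an all-masked FES")
        shift = self.values[~self.mask].min()
        vals = self.values - shift
        vals[self.mask] = np.nan
        return replace(self, values=vals)


def _histogram_window(series: TimeSeries, grid: GridSpec) -> tuple[np.ndarray, int]:
    """Bin one window's samples; return (counts grid, n samples outside grid)."""
    h, _, _ = np.histogram2d(series.xi1, series.xi2, bins=[grid.edges1, grid.edges2])
    inside = int(h.sum())
    return h, len(series) - inside


def _bias_matrix(windows: list[Window], grid: GridSpec) -> np.ndarray:
    """Bias energies (n_windows, n_bins) evaluated at bin centers, row-major bins."""
    c1 = grid.centers1[:, None]          # (bins1, 1)
    c2 = grid.centers2[None, :]          # (1, bins2)
    out = np.empty((len(windows), grid.bins1 * grid.bins2))
    for i, w in enumerate(windows):
        out[i] = w.bias(c1, c2).ravel()
    return out


def _connectivity_check(occupied_per_window: list[np.ndarray], windows: list[Window]) -> None:
    """Raise if the windows' histograms split into disconnected bin-sharing groups."""
    n = len(windows)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    first_window_for_bin: dict[int, int] = {}
    for i, bins in enumerate(occupied_per_window):
        for b in bins.tolist():
            j = first_window_for_bin.setdefault(b, i)
            if j != i:
                parent[find(i)] = find(j)
    roots = {find(i) for i in range(n)}
    if len(roots) > 1:
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        reps = [g[0] for g in groups.values()]
        pairs = [(windows[a].label or a, windows[b].label or b) for a, b in zip(reps, reps[1:])]
        raise ValueError(
            f"window histograms form {len(roots)} disconnected groups; "
            f"no histogram overlap between e.g. window pairs {pairs}"
        )


def solve_wham(
    windows: list[Window],
    series_list: list[TimeSeries],
    grid: GridSpec,
    temperature: float = 300.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FES:
    """Self-consistent binned 2D WHAM over umbrella windows.

    Parameters
    ----------
    windows, series_list
        One sample series per window, in matching order.
    grid
        Histogram grid; samples outside it are counted and reported on the
        returned FES (``n_outside``), never silently dropped.
    temperature
        Kelvin; sets beta for both unbiasing and the energy conversion.
    tol
        Convergence threshold on ``max_i |delta f_i|`` per iteration, kcal/mol.
    max_iter
        Iteration cap; reaching it marks the result ``converged=False``.
    """
    if len(windows) != len(series_list):
        raise ValueError(f"{len(windows)} windows but {len(series_list)} series")
    if not windows:
        raise ValueError("no windows given")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    for w, s in zip(windows, series_list):
        if len(s) == 0:
            raise ValueError(f"empty series for window {w.label!r}")
        if not (np.isfinite(s.xi1).all() and np.isfinite(s.xi2).all()):
            raise ValueError(f"non-finite sample in series for window {w.label!r}")

    beta = 1.0 / (KB * temperature)
    n_win = len(windows)
    n_bins = grid.bins1 * grid.bins2

    counts = np.zeros(n_bins)
    n_samples = np.empty(n_win)
    n_outside = 0
    occupied_per_window: list[np.ndarray] = []
    for i, s in enumerate(series_list):
        h, out = _histogram_window(s, grid)
        h = h.ravel()
        counts += h
        n_samples[i] = h.sum()
        n_outside += out
        occupied_per_window.append(np.nonzero(h)[0])
        if h.sum() == 0:
            raise ValueError(f"no samples of window {s.label or i} land on the grid")
    if n_outside:
        logger.warning("%d samples fell outside the WHAM grid and were excluded", n_outside)
    if counts.sum() == 0:
        raise ValueError("no samples land on the grid: all-masked result")
    _connectivity_check(occupied_per_window, windows)

    occ = counts > 0                     # only occupied bins can carry probability
    bias = _bias_matrix(windows, grid)[:, occ]            # (n_win, n_occ)
    boltz = np.exp(-beta * bias)                          # exp(-beta b_il)
    m_occ = counts[occ]

    f = np.zeros(n_win)
    max_change = math.inf
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        denom = (n_samples * np.exp(beta * f)) @ boltz    # (n_occ,)
        p = m_occ / denom
        with np.errstate(divide="ignore"):
            f_new = -KB * temperature * np.log(boltz @ p)
        f_new -= f_new[0]                                 # gauge: f of first window = 0
        max_change = float(np.abs(f_new - f).max())
        history.append(max_change)
        f = f_new
        if max_change < tol:
            break
    converged = max_change < tol
    if not converged:
        logger.warning(
            "WHAM did not converge in %d iterations (max |delta f| = %.3g kcal/mol)",
            max_iter, max_change,
        )

    denom = (n_samples * np.exp(beta * f)) @ boltz
    p = m_occ / denom
    p /= p.sum()
    g_occ = -KB * temperature * np.log(p)
    g_occ -= g_occ.min()

    values = np.full(n_bins, np.nan)
    values[occ] = g_occ
    mask = ~occ
    return FES(
        values=values.reshape(grid.bins1, grid.bins2),
        mask=mask.reshape(grid.bins1, grid.bins2),
        grid=grid,
        temperature=temperature,
        window_offsets=f,
        iterations=it,
        converged=converged,
        final_max_change=max_change,
        n_outside=n_outside,
        convergence_history=np.array(history),
    )


def _adjacent_pairs(windows: list[Window]) -> list[tuple[int, int]]:
    """Window pairs that are grid neighbors.

    Windows laid out on a regular grid of centers are paired along each axis;
    for irregular layouts each window is paired with its nearest neighbor.
    """
    centers = np.array([w.center for w in windows])
    u1 = np.unique(np.round(centers[:, 0], 9))
    u2 = np.unique(np.round(centers[:, 1], 9))
    pairs: set[tuple[int, int]] = set()
    if len(u1) * len(u2) == len(windows):
        index = {}
        for i, c in enumerate(centers):
            r = int(np.searchsorted(u1, round(c[0], 9)))
            s = int(np.searchsorted(u2, round(c[1], 9)))
            index[(r, s)] = i
        for (r, s), i in index.items():
            for dr, ds in ((1, 0), (0, 1)):
                j = index.get((r + dr, s + ds))
                if j is not None:
                    pairs.add((min(i, j), max(i, j)))
    if not pairs and len(windows) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(centers)
        _, nn = tree.query(centers, k=2)
        for i, j in enumerate(nn[:, 1]):
            pairs.add((min(i, int(j)), max(i, int(j))))
    return sorted(pairs)


def overlap_report(
    windows: list[Window],
    series_list: list[TimeSeries],
    grid: GridSpec,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Histogram-overlap diagnostics for adjacent window pairs.

    Overlap is the histogram intersection ``sum_l min(h_i(l), h_j(l))`` of the
    two windows' normalized histograms; pairs below ``floor`` are flagged.
    A single window yields an empty table.
    """
    if len(windows) != len(series_list):
        raise ValueError(f"{len(windows)} windows but {len(series_list)} series")
    hists = []
    for s in series_list:
        h, _ = _histogram_window(s, grid)
        tot = h.sum()
        hists.append(h.ravel() / tot if tot else h.ravel())
    rows = []
    for i, j in _adjacent_pairs(windows):
        ov = float(np.minimum(hists[i], hists[j]).sum())
        rows.append(
            {
                "window_i": windows[i].label or str(i),
                "window_j": windows[j].label or str(j),
                "overlap": ov,
                "flagged": ov < floor,
            }
        )
    return pd.DataFrame(rows, columns=["window_i", "window_j", "overlap", "flagged"])
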