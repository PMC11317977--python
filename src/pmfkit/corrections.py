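"""Low-level -> high-level energy corrections for profiles and paths.

Free-energy surfaces from an inexpensive (e.g. semiempirical) potential are
corrected by subtracting the reactive-region energy recomputed at the low
level and adding the corresponding high-level (e.g. DFT) single-point
energy; each state's free energy becomes G + (e_high - e_low).  The energies
arrive as plain tables — this module never runs a quantum-chemistry engine.

Two modes: stationary points only (the default; one correction per labeled
state of a profile) and whole-path correction, where a table covering a
subset of path nodes is linearly interpolated in arc length, with
interpolated nodes flagged.  A uniform correction cancels in every barrier;
only state-to-state differences of (e_high - e_low) matter.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .analysis import EnergyProfile, Path

__all__ = ["apply_correction", "correct_path"]


def apply_correction(profile: EnergyProfile, table: dict) -> EnergyProfile:
    """Return a corrected copy of a profile; the original is left untouched.

    ``table`` maps every state label to ``(e_low, e_high)`` in kcal/mol;
    missing labels are enumerated in the error.
    """
    missing = [s.label for s in profile.states if s.label not in table]
    if missing:
        raise ValueError(f"correction table is missing states: {missing}")
    states = []
    for s in profile.states:
        e_low, e_high = table[s.label]
        if not (np.isfinite(e_low) and np.isfinite(e_high)):
            raise ValueError(f"non-finite correction energies for state {s.label!r}")
        states.append(replace(s, energy=s.energy + (e_high - e_low)))
    return EnergyProfile(states=states, name=profile.name)


def correct_path(path: Path, table: dict) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise corrected energies along an MFEP.

    ``table`` maps path node indices (0-based positions along the path) to
    ``(e_low, e_high)``.  Nodes it covers get their exact correction; the
    rest receive the linear interpolation of (e_high - e_low) in arc length
    between the nearest covered nodes (constant extrapolation beyond the
    outermost covered nodes).  Returns ``(corrected_energies,
    interpolated_flags)``, both of path length.
    """
    if not table:
        raise ValueError("empty correction table")
    n = len(path.nodes)
    bad = [k for k in table if not (0 <= int(k) < n)]
    if bad:
        raise ValueError(f"correction table keys outside path (length {n}): {bad}")
    seg = np.zeros(n)
    if n > 1:
        steps = np.linalg.norm(np.diff(path.positions, axis=0), axis=1)
        seg[1:] = np.cumsum(steps)
    known_idx = np.array(sorted(int(k) for k in table))
    known_delta = np.array([table[int(k)][1] - table[int(k)][0] for k in known_idx])
    delta = np.interp(seg, seg[known_idx], known_delta)
    flags = np.ones(n, dtype=bool)
    flags[known_idx] = False
    return path.energies + delta, flags
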