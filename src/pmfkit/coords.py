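"""Distance-based reaction coordinates on Cartesian frames.

Serine-hydrolase mechanisms are followed here along two kinds of collective
coordinate: a single interatomic distance (e.g. the nucleophile-to-carbonyl
attack distance) and the antisymmetric combination of two distances
d(a) - d(b), the standard proton-transfer coordinate (donor-H minus
acceptor-H).  Atoms are addressed by PDB serial number; resolving names like
"Ser134 OG" to serials is the job of the I/O layer.

No periodic-boundary minimum-image convention is applied: the coordinates of
interest are intra-active-site distances of a few angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CoordinateDef", "Frame", "distance", "antisym", "evaluate_series"]


@dataclass(frozen=True)
class CoordinateDef:
    """One reaction coordinate: a distance or an antisymmetric difference.

    ``pairs`` holds one serial pair for kind="distance" and exactly two for
    kind="antisym"; the first-listed pair enters with positive sign.
    """

    kind: str
    pairs: tuple[tuple[int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "antisym"):
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        want = 1 if self.kind == "distance" else 2
        if len(self.pairs) != want:
            raise ValueError(f"{self.kind} coordinate needs {want} atom pair(s), got {len(self.pairs)}")
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"degenerate atom pair ({i}, {j}) in {self.label or self.kind}")


@dataclass
class Frame:
    """Cartesian coordinates (A) indexed by atom serial."""

    serials: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.serials = np.asarray(self.serials, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.serials), 3)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in frame")
        self._index = {int(s): i for i, s in enumerate(self.serials)}
        if len(self._index) != len(self.serials):
            raise ValueError("duplicate serials in frame")

    def position(self, serial: int) -> np.ndarray:
        try:
            return self.coords[self._index[serial]]
        except KeyError:
            raise KeyError(f"no atom with serial {serial} in frame") from None


def distance(frame: Frame, i: int, j: int) -> float:
    """Euclidean distance (A) between atoms with serials i and j."""
    if i == j:
        raise ValueError(f"distance requested between atom {i} and itself")
    return float(np.linalg.norm(frame.position(i) - frame.position(j)))


def antisym(
    frame: Frame, pair_a: tuple[int, int], pair_b: tuple[int, int]
) -> float:
    """Antisymmetric distance combination d(pair_a) - d(pair_b), in A."""
    return distance(frame, *pair_a) - distance(frame, *pair_b)


def evaluate_coordinate(frame: Frame, cdef: CoordinateDef) -> float:
    if cdef.kind == "distance":
        return distance(frame, *cdef.pairs[0])
    return antisym(frame, cdef.pairs[0], cdef.pairs[1])


def evaluate_series(frames, defs) -> pd.DataFrame:
    """Evaluate every coordinate definition on every frame, frame order preserved.

    Returns a DataFrame with one column per definition (named by its label,
    or ``kind#index`` when unlabeled).  The first failing (frame, definition)
    is reported with both indices.
    """
    cols = [d.label or f"{d.kind}#{k}" for k, d in enumerate(defs)]
    rows = []
    for fi, frame in enumerate(frames):
        row = []
        for d, name in zip(defs, cols):
            try:
                row.append(evaluate_coordinate(frame, d))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"frame {fi}, coordinate {name!r}: {exc}") from exc
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
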