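"""On-disk formats for the free-energy pipeline.

Everything is plain text, energies in kcal/mol, lengths in angstrom; no unit
autodetection.  The formats are:

* **window metadata** — one window per non-comment line:
  ``series_file  center1  center2  k1  k2`` (the multi-column metadata-file
  convention of grid WHAM tools, so third-party umbrella data can be
  ingested);
* **time series** — whitespace-separated ``index  xi1  xi2`` columns;
* **FES grid** — '#'-prefixed header (ranges, bins, temperature, mask
  sentinel) followed by the free energies in row-major order (axis-1 bins as
  rows), ``nan`` marking never-visited bins;
* **charge system** — a PDB coordinate file plus a tab-separated charge
  table (serial, chain, resSeq, iCode, resName, charge, qm_flag); charges
  live outside the PDB because the PDB format has no charge column with
  usable precision, and occupancy/B-factor are never repurposed;
* **correction table** — JSON mapping state label to ``{"e_low": ..,
  "e_high": ..}``;
* **run config** — JSON.

Readers never silently drop records: every skipped or rejected line is
reported with its location.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .analysis import EnergyProfile, ProfileState
from .decomposition import ChargeSystem
from .wham import FES, GridSpec, TimeSeries, Window

__all__ = [
    "write_window_metadata",
    "read_window_metadata",
    "write_time_series",
    "read_time_series",
    "write_fes",
    "read_fes",
    "write_charge_system",
    "read_charge_system",
    "write_correction_table",
    "read_correction_table",
    "write_profile",
    "read_profile",
]

CHARGE_TABLE_COLUMNS = ["serial", "chain", "resSeq", "iCode", "resName", "charge", "qm_flag"]


# ---------------------------------------------------------------- windows

def write_window_metadata(windows, series_paths, path) -> None:
    """Write the window metadata file; series paths are recorded as given."""
    if len(windows) != len(series_paths):
        raise ValueError("one series path per window required")
    lines = ["# series_file  center1  center2  k1  k2"]
    for w, sp in zip(windows, series_paths):
        c1, c2 = w.center
        k1, k2 = w.force_constants
        lines.append(f"{sp} {c1:.17g} {c2:.17g} {k1:.17g} {k2:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_window_metadata(path) -> tuple[list[Window], list[str]]:
    """Read windows and their series-file paths, in file order.

    Comment lines (leading '#') and blank lines are ignored; a file with no
    data lines yields an empty list with a warning.  Malformed lines report
    the file, line number, and offending field; non-positive force constants
    are rejected.
    """
    path = Path(path)
    windows: list[Window] = []
    series_paths: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 fields "
                    f"(series_file center1 center2 k1 k2), got {len(parts)}"
                )
            vals = []
            for field_idx, token in enumerate(parts[1:], start=2):
                try:
                    vals.append(float(token))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: field {field_idx} is not numeric: {token!r}"
                    ) from None
            c1, c2, k1, k2 = vals
            if k1 <= 0 or k2 <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive force constant ({k1}, {k2})")
            windows.append(
                Window(center=(c1, c2), force_constants=(k1, k2), label=f"w{len(windows):04d}")
            )
            series_paths.append(parts[0])
    if not windows:
        warnings.warn(f"{path}: no window definitions found (comments only)", stacklevel=2)
    return windows, series_paths


# ------------------------------------------------------------ time series

def write_time_series(series: TimeSeries, path) -> None:
    with Path(path).open("w") as fh:
        for i, (a, b) in enumerate(zip(series.xi1, series.xi2)):
            fh.write(f"{i} {a:.17g} {b:.17g}\n")


def read_time_series(path, label: str = "") -> TimeSeries:
    """Read an ``index xi1 xi2`` series; NaN or non-numeric cells are errors."""
    path = Path(path)
    xi1: list[float] = []
    xi2: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns, got {len(parts)}")
            try:
                a, b = float(parts[1]), float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate cell") from None
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"{path}:{lineno}: non-finite coordinate value")
            xi1.append(a)
            xi2.append(b)
    return TimeSeries(xi1=np.array(xi1), xi2=np.array(xi2), label=label or path.stem)


# -------------------------------------------------------------------- FES

def write_fes(fes: FES, path) -> None:
    """Write an FES grid as text; masked bins serialize as ``nan``."""
    g = fes.grid
    header = (
        "# pmfkit FES v1\n"
        f"# range1 {g.range1[0]:.17g} {g.range1[1]:.17g}\n"
        f"# range2 {g.range2[0]:.17g} {g.range2[1]:.17g}\n"
        f"# bins {g.bins1} {g.bins2}\n"
        f"# temperature {fes.temperature:.10g}\n"
        "# mask_sentinel nan\n"
        "# layout row-major: one row per axis-1 bin, columns are axis-2 bins\n"
    )
    vals = fes.values.copy()
    vals[fes.mask] = np.nan
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_fes(path) -> FES:
    path = Path(path)
    meta: dict[str, list[str]] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts:
                    meta[parts[0]] = parts[1:]
                continue
            try:
                rows.append([float(t) for t in line.split()])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric grid value") from None
    for key in ("range1", "range2", "bins", "temperature"):
        if key not in meta:
            raise ValueError(f"{path}: missing header field '{key}'")
    grid = GridSpec(
        range1=(float(meta["range1"][0]), float(meta["range1"][1])),
        range2=(float(meta["range2"][0]), float(meta["range2"][1])),
        bins1=int(meta["bins"][0]),
        bins2=int(meta["bins"][1]),
    )
    values = np.array(rows, dtype=float)
    if values.shape != (grid.bins1, grid.bins2):
        raise ValueError(
            f"{path}: grid shape {values.shape} does not match header bins "
            f"({grid.bins1}, {grid.bins2})"
        )
    return FES(
        values=values,
        mask=np.isnan(values),
        grid=grid,
        temperature=float(meta["temperature"][0]),
    )


# ---------------------------------------------------------- charge system

def write_charge_system(system: ChargeSystem, pdb_path, table_path) -> None:
    """Write coordinates as fixed-column PDB records plus the charge table."""
    with Path(pdb_path).open("w") as fh:
        for i in range(len(system)):
            record = "HETATM" if system.qm_mask[i] else "ATOM  "
            name = f"X{i % 99:<3d}"[:4]
            fh.write(
                f"{record}{system.serial[i]:>5d} {name:<4s} {str(system.resName[i])[:3]:>3s} "
                f"{str(system.chain[i])[:1]:1s}{system.resSeq[i]:>4d}{str(system.iCode[i])[:1] or ' ':1s}   "
                f"{system.coords[i, 0]:8.3f}{system.coords[i, 1]:8.3f}{system.coords[i, 2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}\n"
            )
        fh.write("END\n")
    df = pd.DataFrame(
        {
            "serial": system.serial,
            "chain": system.chain,
            "resSeq": system.resSeq,
            "iCode": ["." if not c else c for c in system.iCode],
            "resName": system.resName,
            "charge": system.charge,
            "qm_flag": system.qm_mask.astype(int),
        }
    )
    df.to_csv(table_path, sep="\t", index=False, float_format="%.10g")


def read_charge_system(pdb_path, table_path) -> ChargeSystem:
    """Assemble a ChargeSystem from a PDB file and a TSV charge table.

    Every PDB atom must match exactly one charge row by serial; unmatched
    serials on either side are listed exhaustively.  Alternate locations
    other than blank/'A' are rejected: the decomposition needs one geometry
    per state.  The '.' token in the iCode column means "no insertion code".
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # toy PDBs trigger benign element-guess warnings
        structure = PDBParser(QUIET=True).get_structure("system", str(pdb_path))
    serials: list[int] = []
    coords: list[np.ndarray] = []
    for atom in structure.get_atoms():
        altloc = atom.get_altloc()
        if altloc not in (" ", "A"):
            raise ValueError(
                f"{pdb_path}: atom serial {atom.get_serial_number()} has altLoc "
                f"{altloc!r}; only blank or 'A' is accepted (one geometry per state)"
            )
        serials.append(int(atom.get_serial_number()))
        coords.append(atom.get_coord().astype(float))
    if not serials:
        raise ValueError(f"{pdb_path}: no ATOM/HETATM records found")
    serial_arr = np.array(serials)
    if len(np.unique(serial_arr)) != len(serial_arr):
        dupes = sorted(set(s for s in serials if serials.count(s) > 1))
        raise ValueError(f"{pdb_path}: duplicate atom serials {dupes}")

    table = pd.read_csv(table_path, sep="\t", dtype={"chain": str, "iCode": str, "resName": str})
    missing_cols = [c for c in CHARGE_TABLE_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"{table_path}: missing columns {missing_cols}")
    if table["serial"].duplicated().any():
        dupes = sorted(table.loc[table["serial"].duplicated(), "serial"].unique().tolist())
        raise ValueError(f"{table_path}: duplicate serials {dupes}")
    table = table.set_index("serial")
    pdb_set = set(serial_arr.tolist())
    tbl_set = set(table.index.tolist())
    unmatched_pdb = sorted(pdb_set - tbl_set)
    unmatched_tbl = sorted(tbl_set - pdb_set)
    if unmatched_pdb or unmatched_tbl:
        raise ValueError(
            f"serial mismatch between {pdb_path} and {table_path}: "
            f"PDB atoms without charge rows: {unmatched_pdb}; "
            f"charge rows without PDB atoms: {unmatched_tbl}"
        )
    table = table.loc[serial_arr]
    icode = table["iCode"].fillna("").replace(".", "").astype(str).to_numpy(dtype=object)
    return ChargeSystem(
        serial=serial_arr,
        coords=np.array(coords),
        charge=table["charge"].to_numpy(dtype=float),
        chain=table["chain"].to_numpy(dtype=object),
        resSeq=table["resSeq"].to_numpy(dtype=int),
        iCode=icode,
        resName=table["resName"].to_numpy(dtype=object),
        qm_mask=table["qm_flag"].to_numpy(dtype=int).astype(bool),
    )


# ------------------------------------------------------- correction table

def write_correction_table(table: dict, path, units: str = "kcal/mol") -> None:
    payload = {
        "units": units,
        "states": {
            label: {"e_low": float(v[0]), "e_high": float(v[1])}
            for label, v in table.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_profile(profile: EnergyProfile, path) -> None:
    payload = {
        "name": profile.name,
        "states": [
            {"label": s.label, "energy": s.energy, "kind": s.kind, "branch": s.branch}
            for s in profile.states
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_profile(path) -> EnergyProfile:
    payload = json.loads(Path(path).read_text())
    return EnergyProfile(
        states=[
            ProfileState(
                label=s["label"],
                energy=float(s["energy"]),
                kind=s["kind"],
                branch=s.get("branch"),
            )
            for s in payload["states"]
        ],
        name=payload.get("name", ""),
    )


def read_correction_table(path) -> dict:
    """Read a JSON correction table into ``{label: (e_low, e_high)}``."""
    payload = json.loads(Path(path).read_text())
    units = payload.get("units", "kcal/mol")
    if units != "kcal/mol":
        raise ValueError(f"{path}: correction table declares units {units!r}; expected kcal/mol")
    out = {}
    for label, v in payload["states"].items():
        if not (np.isfinite(v["e_low"]) and np.isfinite(v["e_high"])):
            raise ValueError(f"{path}: non-finite energies for state {label!r}")
        out[label] = (float(v["e_low"]), float(v["e_high"]))
    return out
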