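"""Trajectory, event-table and scalar-grid I/O.

Formats handled: multi-model PDB (one MODEL per frame), XYZ frame series,
TSV event tables (tab-separated, header required), OpenDX scalar grids and
JSON sidecars.  Readers validate internal consistency and reject rather
than repair broken inputs.  Coordinates are Å throughout; times are ns
internally, with the trajectory stride expressed in ps at the boundary
(the MD convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .constants import PS_PER_NS

__all__ = [
    "Trajectory",
    "EventTable",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_events_tsv",
    "write_events_tsv",
]


@dataclass
class Trajectory:
    """A frame series of labelled atom coordinates at fixed stride.

    Attributes
    ----------
    times : (n_frames,) ns, strictly increasing, constant stride.
    atoms : DataFrame with columns name, resname, resnum, chain — identical
        for every frame.
    coords : (n_frames, n_atoms, 3) Å.
    provenance : free-form dict recording source path, stride etc.
    """

    times: np.ndarray
    atoms: pd.DataFrame
    coords: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] != self.times.size:
            raise ValueError("frame count of coords and times differ")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom count of coords and atom table differ")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("stride must be constant to within 1e-6 ns")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def stride_ns(self) -> float:
        if self.times.size < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    def atom_index(self, name: str) -> int:
        """Index of the first atom with the given atom name."""
        idx = np.flatnonzero(self.atoms["name"].to_numpy() == name)
        if idx.size == 0:
            raise KeyError(f"no atom named {name!r} in trajectory")
        return int(idx[0])


@dataclass
class EventTable:
    """Residence events: one row per run with duration and censoring flag.

    A censored row means the particle had not left the region when the run
    (or the observation cutoff) ended; its duration equals the cutoff.
    """

    events: pd.DataFrame  # columns: run_id, duration_ns, censored
    cutoff_ns: float | None = float("inf")  # None: per-event (trajectory-end)

    def __post_init__(self) -> None:
        required = {"run_id", "duration_ns", "censored"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        self.events = self.events.reset_index(drop=True)
        self.events["duration_ns"] = self.events["duration_ns"].astype(float)
        self.events["censored"] = self.events["censored"].astype(bool)
        dur = self.events["duration_ns"].to_numpy()
        if np.any(~np.isfinite(dur)) or np.any(dur <= 0):
            raise ValueError("durations must be positive and finite")
        cens = self.events["censored"].to_numpy()
        if self.cutoff_ns is None:
            return  # censoring times vary per event (e.g. trajectory end)
        if np.isfinite(self.cutoff_ns):
            bad = cens & (np.abs(dur - self.cutoff_ns) > 1e-9)
            if np.any(bad):
                raise ValueError(
                    "censored events must have duration equal to the cutoff "
                    f"({self.cutoff_ns} ns); offending run_ids: "
                    f"{self.events.loc[bad, 'run_id'].tolist()}"
                )
        elif np.any(cens):
            raise ValueError("censored events require a finite cutoff")

    @property
    def n_runs(self) -> int:
        return len(self.events)

    @property
    def n_escapes(self) -> int:
        return int((~self.events["censored"]).sum())

    @property
    def n_censored(self) -> int:
        return int(self.events["censored"].sum())

    def durations(self, censored: bool | None = None) -> np.ndarray:
        """Durations (ns), optionally restricted by censoring status."""
        if censored is None:
            return self.events["duration_ns"].to_numpy()
        mask = self.events["censored"].to_numpy() == censored
        return self.events.loc[mask, "duration_ns"].to_numpy()


# ---------------------------------------------------------------------------
# multi-model PDB


def _scan_pdb_model_atom_counts(path: Path) -> list[int]:
    """Per-MODEL ATOM/HETATM record counts; a file without MODEL records is
    treated as a single model."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                counts.append(0)
                current = len(counts) - 1
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    counts.append(0)
                    current = 0
                counts[current] += 1
    return counts


def read_multimodel_pdb(path: str | Path, stride_ps: float | None = None) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Atom identity is taken from the first model and must match every other
    model; a mismatch is reported with the offending model index.  Times are
    assigned from ``stride_ps`` (default 50 ps).
    """
    path = Path(path)
    counts = _scan_pdb_model_atom_counts(path)
    if not counts or all(c == 0 for c in counts):
        raise ValueError(f"{path}: no models with atoms found")
    ref = counts[0]
    for i, c in enumerate(counts[1:], start=2):
        if c != ref:
            raise ValueError(
                f"{path}: model {i} has {c} atoms, expected {ref} "
                "(atom count must match the first model)"
            )
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack; biotite enforces columns
    atoms = pd.DataFrame(
        {
            "name": stack.atom_name,
            "resname": stack.res_name,
            "resnum": stack.res_id,
            "chain": stack.chain_id,
        }
    )
    stride = 50.0 if stride_ps is None else float(stride_ps)
    times = np.arange(stack.stack_depth()) * stride / PS_PER_NS
    return Trajectory(
        times=times,
        atoms=atoms,
        coords=np.asarray(stack.coord, dtype=float),
        provenance={"source": str(path), "stride_ps": stride, "format": "pdb"},
    )


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    n = traj.n_atoms
    arr = bst.AtomArrayStack(traj.n_frames, n)
    arr.coord = traj.coords.astype(np.float32)
    arr.atom_name = traj.atoms["name"].to_numpy(dtype="U6")
    arr.res_name = traj.atoms["resname"].to_numpy(dtype="U5")
    arr.res_id = traj.atoms["resnum"].to_numpy(dtype=int)
    arr.chain_id = traj.atoms["chain"].to_numpy(dtype="U4")
    arr.element = np.array(
        [name.strip()[:1] for name in traj.atoms["name"]], dtype="U2"
    )
    arr.hetero = np.ones(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ


def read_xyz_trajectory(path: str | Path, stride_ps: float = 50.0) -> Trajectory:
    """Read a (possibly multi-frame) XYZ file.

    Element symbols become atom names; times are assigned from the stride.
    Ragged frames (inconsistent atom counts) and non-numeric coordinates
    are rejected.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    names: list[str] | None = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}: frame {frame_no}: bad atom-count line {i + 1}")
        if i + 1 + n >= len(lines) + 1:
            raise ValueError(f"{path}: frame {frame_no} truncated")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: frame {frame_no} truncated")
        fnames, coords = [], []
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: frame {frame_no}, atom {j + 1}: short line")
            fnames.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise ValueError(
                    f"{path}: frame {frame_no}, atom {j + 1}: non-numeric coordinate"
                )
        if names is None:
            names = fnames
        elif len(fnames) != len(names):
            raise ValueError(
                f"{path}: frame {frame_no} has {len(fnames)} atoms, "
                f"expected {len(names)}"
            )
        frames.append(np.array(coords))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    atoms = pd.DataFrame(
        {
            "name": names,
            "resname": ["UNK"] * len(names),
            "resnum": [1] * len(names),
            "chain": ["A"] * len(names),
        }
    )
    times = np.arange(len(frames)) * float(stride_ps) / PS_PER_NS
    return Trajectory(
        times=times,
        atoms=atoms,
        coords=np.stack(frames),
        provenance={"source": str(path), "stride_ps": float(stride_ps), "format": "xyz"},
    )


def write_xyz_trajectory(traj: Trajectory, path: str | Path, comment: str = "") -> None:
    names = traj.atoms["name"].tolist()
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment}\n")
            for name, (x, y, z) in zip(names, traj.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# event tables


def read_events_tsv(path: str | Path) -> EventTable:
    """Read a residence-event TSV (columns run_id, duration_ns, censored).

    The cutoff is read from a ``# cutoff_ns = <value>`` comment line when
    present; otherwise it is inferred as the common duration of censored
    rows (infinite if nothing is censored).  EventTable invariants are
    enforced on read.
    """
    path = Path(path)
    cutoff = None
    with open(path) as fh:
        head = [next(fh, "") for _ in range(5)]
    for ln in head:
        if ln.startswith("#") and "cutoff_ns" in ln:
            cutoff = float(ln.split("=")[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"run_id", "duration_ns", "censored"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")
    if cutoff is None:
        cens = df["censored"].astype(bool)
        cutoff = float(df.loc[cens, "duration_ns"].iloc[0]) if cens.any() else float("inf")
    return EventTable(events=df, cutoff_ns=cutoff)


def write_events_tsv(table: EventTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        if np.isfinite(table.cutoff_ns):
            fh.write(f"# cutoff_ns = {table.cutoff_ns:g}\n")
        table.events.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OpenDX scalar grids


def write_density_dx(grid, path: str | Path, field_name: str = "density") -> None:
    """Write a voxel grid as an OpenDX scalar field (for isosurface viewers).

    ``grid`` is any object with ``origin`` (minimum box corner, Å),
    ``spacing`` (Å) and either ``probability`` or ``values`` per voxel.
    The DX grid positions are the voxel centers, so the written origin is
    ``grid.origin + spacing/2``; data follow in row-major order (z fastest),
    the order the format declares.
    """
    values = getattr(grid, "probability", None)
    if values is None:
        values = grid.values
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty grid")
    nx, ny, nz = values.shape
    ox, oy, oz = np.asarray(grid.origin, dtype=float) + grid.spacing / 2.0
    s = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {s:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {s:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {s:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} "
            "data follows\n"
        )
        flat = values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.10e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write(f'object "{field_name}" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def write_json_sidecar(obj: dict, path: str | Path) -> None:
    """Write generator/analysis settings next to a data artifact."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
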