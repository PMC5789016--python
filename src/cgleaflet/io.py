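"""Coordinate containers, GRO round-trip and leaflet assignment.

Coordinates are in nm throughout, z is the membrane normal, and the xy
plane is periodic with the box (half-open cell convention for all
binning).  GRO files are read and written through MDAnalysis behind this
surface; a light pre-validation produces the format errors callers are
promised (header/bead-count mismatch, malformed fixed columns).
"""

from __future__ import annotations

import glob as _glob
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .topology import LipidTopology

__all__ = [
    "Frame",
    "Trajectory",
    "LeafletAssignment",
    "GroFormatError",
    "LeafletError",
    "read_gro",
    "write_gro",
    "read_trajectory",
    "write_trajectory",
    "assign_leaflets",
    "analysis_window",
]


class GroFormatError(ValueError):
    """Malformed GRO file (bad header count or line layout)."""


class LeafletError(ValueError):
    """Leaflet assignment impossible (not a planar bilayer)."""


@dataclass
class Frame:
    """One configuration: positions plus parallel per-bead annotation arrays."""

    positions: np.ndarray  # (n, 3) float64, nm
    box: np.ndarray  # (3,) float64, nm
    names: np.ndarray  # (n,) str
    resnames: np.ndarray  # (n,) str
    resids: np.ndarray  # (n,) int
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        n = len(self.positions)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive lengths")
        for arr, label in (
            (self.names, "names"),
            (self.resnames, "resnames"),
            (self.resids, "resids"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != {n} positions")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "Frame":
        return Frame(
            self.positions.copy(),
            self.box.copy(),
            self.names.copy(),
            self.resnames.copy(),
            self.resids.copy(),
            self.time,
        )

    def select(self, mask: np.ndarray) -> "Frame":
        """Sub-frame of the beads where ``mask`` is true."""
        return Frame(
            self.positions[mask],
            self.box.copy(),
            self.names[mask],
            self.resnames[mask],
            self.resids[mask],
            self.time,
        )


@dataclass
class Trajectory:
    """Ordered frames with a shared bead layout and strictly increasing times."""

    frames: list[Frame]
    topology: LipidTopology | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = self.frames[0].n_beads
        times = [f.time for f in self.frames]
        for f in self.frames:
            if f.n_beads != n:
                raise ValueError("bead count varies across frames")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i], self.topology)
        return self.frames[i]


@dataclass
class LeafletAssignment:
    """Total partition of lipid resids into upper and lower leaflets."""

    upper: np.ndarray  # sorted lipid resids
    lower: np.ndarray
    midplane_z: float = 0.0

    def leaflet_of(self, resid: int) -> str:
        if resid in set(self.upper.tolist()):
            return "upper"
        if resid in set(self.lower.tolist()):
            return "lower"
        raise KeyError(f"resid {resid} is not an assigned lipid")

    def resids(self, leaflet: str) -> np.ndarray:
        if leaflet == "upper":
            return self.upper
        if leaflet == "lower":
            return self.lower
        raise ValueError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")


# --------------------------------------------------------------------------
# GRO round trip (MDAnalysis under the hood; Angstrom <-> nm conversion here)
# --------------------------------------------------------------------------


def _prevalidate_gro(path: str) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GroFormatError(f"{path}: fewer than 3 lines")
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise GroFormatError(f"{path}: bead-count header is not an integer") from None
    if len(lines) != n + 3:
        raise GroFormatError(
            f"{path}: header says {n} beads but file has {len(lines) - 3} atom lines"
        )
    for i, line in enumerate(lines[2 : 2 + n]):
        if len(line) < 44:
            raise GroFormatError(f"{path}: atom line {i + 3} shorter than 44 columns")


def _parse_time_ps(title: str) -> float:
    if "t=" in title:
        try:
            return float(title.split("t=")[-1].split()[0])
        except (ValueError, IndexError):
            pass
    return 0.0


def read_gro(path) -> Frame:
    """Read a single-frame GRO file into a Frame (nm)."""
    import MDAnalysis as mda

    path = os.fspath(path)
    _prevalidate_gro(path)
    with open(path) as fh:
        title = fh.readline().rstrip("\n")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
        box = u.dimensions
        if box is None or np.any(box[:3] <= 0):
            raise GroFormatError(f"{path}: missing or degenerate box vector line")
        return Frame(
            positions=u.atoms.positions.astype(float) / 10.0,
            box=np.asarray(box[:3], dtype=float) / 10.0,
            names=np.array(u.atoms.names, dtype=object),
            resnames=np.array(u.atoms.resnames, dtype=object),
            resids=np.array(u.atoms.resids, dtype=int),
            time=_parse_time_ps(title),
        )


def write_gro(frame: Frame, path, title: str | None = None) -> None:
    """Write a Frame as a fixed-column GRO file (nm, 3 decimals)."""
    import MDAnalysis as mda

    path = os.fspath(path)
    n = frame.n_beads
    _, res_index = np.unique(frame.resids, return_inverse=True)
    # preserve first-occurrence residue order, not sorted-resid order
    order = np.zeros(res_index.max() + 1, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(res_index):
        if r not in seen:
            seen[r] = len(seen)
        order[r] = seen[r]
    res_index = order[res_index]
    n_res = res_index.max() + 1
    res_resids = np.zeros(n_res, dtype=int)
    res_resnames = np.empty(n_res, dtype=object)
    res_resids[res_index] = frame.resids
    res_resnames[res_index] = frame.resnames

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=n_res, atom_resindex=res_index, trajectory=True
        )
        u.add_TopologyAttr("names", [str(x) for x in frame.names])
        u.add_TopologyAttr("resnames", [str(x) for x in res_resnames])
        u.add_TopologyAttr("resids", res_resids)
        u.atoms.positions = frame.positions * 10.0
        u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
        u.trajectory.ts.data["time"] = frame.time
        u.atoms.write(path)

    if title is None:
        title = f"cgleaflet frame, t= {frame.time:.3f}"
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines[0] = title
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, directory, prefix: str = "frame") -> list[str]:
    """Write a trajectory as numbered single-frame GRO files; returns paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, frame in enumerate(traj):
        p = os.path.join(os.fspath(directory), f"{prefix}_{i:05d}.gro")
        write_gro(frame, p)
        paths.append(p)
    return paths


def read_trajectory(paths, topology: LipidTopology | None = None) -> Trajectory:
    """Read a trajectory from a glob pattern or explicit path list."""
    if isinstance(paths, (str, os.PathLike)):
        paths = sorted(_glob.glob(os.fspath(paths)))
    if not paths:
        raise FileNotFoundError("no trajectory files matched")
    frames = [read_gro(p) for p in paths]
    # files without time stamps: fall back to the file order
    times = [f.time for f in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        for i, f in enumerate(frames):
            f.time = float(i)
    return Trajectory(frames, topology)


# --------------------------------------------------------------------------
# Leaflet assignment and analysis windows
# --------------------------------------------------------------------------


def reference_bead_mask(frame: Frame, topology: LipidTopology) -> np.ndarray:
    """Boolean mask of the single reference bead of every lipid."""
    mask = np.zeros(frame.n_beads, dtype=bool)
    for name, sp in topology.species.items():
        mask |= (frame.resnames == name) & (frame.names == sp.ref_bead)
    return mask


def assign_leaflets(frame: Frame, topology: LipidTopology) -> LeafletAssignment:
    """Partition lipids into leaflets by reference-phosphate z vs midplane.

    The midplane is the mean z of all reference beads; a lipid is upper
    iff its reference bead sits above it.  This assumes a planar bilayer
    whose normal is z — curved membranes need orientation-based methods
    and are out of scope here.
    """
    mask = reference_bead_mask(frame, topology)
    resids = frame.resids[mask]
    z = frame.positions[mask, 2]
    if len(resids) < 2:
        raise LeafletError("fewer than 2 lipids; cannot split into leaflets")
    mid = float(np.mean(z))
    upper = np.sort(resids[z >= mid])
    lower = np.sort(resids[z < mid])
    if len(upper) == 0 or len(lower) == 0:
        raise LeafletError("all reference beads on one side of the midplane; not a bilayer")
    return LeafletAssignment(upper=upper, lower=lower, midplane_z=mid)


def analysis_window(traj: Trajectory, fraction: float = 0.5) -> Trajectory:
    """Trailing fraction of the trajectory used for structural analysis.

    The default keeps the last half of the frames (the production-run
    convention of analysing only the converged tail of a trajectory);
    pass fraction=0.125 for the shorter partial-density window.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(traj)
    start = n - max(1, int(round(n * fraction)))
    return traj[start:]
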