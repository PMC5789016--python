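"""Tail order parameters and leaflet-resolved 2D order maps.

The per-lipid order parameter is the standard second-rank order
P2 = (3<cos^2 theta> - 1) / 2 of consecutive tail-bead bond vectors
against the membrane normal (z), averaged over all bonds of all tails of
the lipid.  Averaging is per-lipid first (mean over bonds), then per
grid cell (mean over lipids and frames), so each lipid carries equal
weight regardless of its tail count — an LPS molecule with six tails
counts once, like a two-tailed POPE.

Maps bin each lipid by its reference-phosphate xy position (periodic,
half-open cells).  Bond vectors use the minimum-image convention, so
molecules split across the periodic boundary are handled.
"""

from __future__ import annotations

import numpy as np

from .grid import GridMismatchError, GridSpec, ScalarMap2D
from .io import Frame, LeafletAssignment, Trajectory, analysis_window, assign_leaflets
from .topology import LipidTopology

__all__ = [
    "lipid_order",
    "species_order",
    "order_map",
    "difference_map",
    "center_on_protein",
]


def _min_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def lipid_order(
    frame: Frame, resid: int, topology: LipidTopology
) -> float:
    """P2 of one lipid: mean bond order over all tails, bonds vs z."""
    mask = frame.resids == resid
    if not mask.any():
        raise KeyError(f"no beads with resid {resid}")
    resname = str(frame.resnames[mask][0])
    sp = topology[resname]
    names = frame.names[mask]
    pos = frame.positions[mask]
    lookup = {str(n): i for i, n in enumerate(names)}
    p2_sum, n_bonds = 0.0, 0
    for chain in sp.tail_chains:
        for b1, b2 in zip(chain, chain[1:]):
            bond = _min_image(pos[lookup[b2]] - pos[lookup[b1]], frame.box)
            norm2 = float(bond @ bond)
            if norm2 == 0.0:
                raise ValueError(f"zero-length bond {b1}-{b2} in resid {resid}")
            p2_sum += 1.5 * bond[2] ** 2 / norm2 - 0.5
            n_bonds += 1
    if n_bonds == 0:
        raise ValueError(f"species {resname} has no tail bonds")
    return p2_sum / n_bonds


def species_order(
    frame: Frame, topology: LipidTopology, species: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-lipid P2 and reference xy for all lipids of a species.

    Returns (resids, p2, ref_xy) sorted by resid.  Relies on every lipid
    of the species carrying the full set of topology bead names exactly
    once, which the GRO convention guarantees.
    """
    sp = topology[species]
    sel_species = frame.resnames == species
    if not sel_species.any():
        raise ValueError(f"species {species!r} absent from frame")

    def _aligned(bead: str) -> np.ndarray:
        m = sel_species & (frame.names == bead)
        resids = frame.resids[m]
        order = np.argsort(resids, kind="stable")
        return frame.positions[m][order], resids[order]

    ref_pos, resids = _aligned(sp.ref_bead)
    n = len(resids)
    p2_sum = np.zeros(n)
    n_bonds = 0
    for chain in sp.tail_chains:
        positions = []
        for bead in chain:
            p, r = _aligned(bead)
            if len(r) != n or not np.array_equal(r, resids):
                raise ValueError(
                    f"species {species!r}: bead {bead} count mismatch with {sp.ref_bead}"
                )
            positions.append(p)
        for p1, p2_ in zip(positions, positions[1:]):
            bond = _min_image(p2_ - p1, frame.box)
            norm2 = np.einsum("ij,ij->i", bond, bond)
            if np.any(norm2 == 0.0):
                raise ValueError(f"zero-length bond in species {species!r}")
            p2_sum += 1.5 * bond[:, 2] ** 2 / norm2 - 0.5
            n_bonds += 1
    return resids, p2_sum / n_bonds, ref_pos[:, :2]


def order_map(
    traj: Trajectory,
    leaflet: str,
    topology: LipidTopology | None = None,
    grid: GridSpec | None = None,
    species: str | tuple[str, ...] | None = None,
    window: float = 0.5,
    assignment: LeafletAssignment | None = None,
) -> ScalarMap2D:
    """Leaflet-resolved 2D order map over the trailing analysis window.

    Each lipid contributes its per-lipid P2 to the cell containing its
    reference phosphate; the cell value is the mean over lipids and
    frames, with the per-cell sample count recorded.
    """
    topology = topology or traj.topology
    if topology is None:
        raise ValueError("a LipidTopology is required")
    win = analysis_window(traj, window)
    grid = grid or GridSpec.for_box(win[0].box)
    if assignment is None:
        assignment = assign_leaflets(win[0], topology)
    wanted = assignment.resids(leaflet)

    if species is None:
        species_list = [s for s in topology.names() if (win[0].resnames == s).any()]
    elif isinstance(species, str):
        species_list = [species]
    else:
        species_list = list(species)

    sums = np.zeros((grid.n_x, grid.n_y))
    counts = np.zeros((grid.n_x, grid.n_y), dtype=int)
    contributed = False
    for frame in win:
        for s in species_list:
            if not (frame.resnames == s).any():
                continue
            resids, p2, xy = species_order(frame, topology, s)
            in_leaflet = np.isin(resids, wanted)
            if not in_leaflet.any():
                continue
            contributed = True
            ix, iy = grid.bin_index(xy[in_leaflet])
            np.add.at(sums, (ix, iy), p2[in_leaflet])
            np.add.at(counts, (ix, iy), 1)
    if not contributed:
        raise ValueError(
            f"no lipids of species {species_list} in the {leaflet} leaflet window"
        )
    values = np.full_like(sums, np.nan)
    occ = counts > 0
    values[occ] = sums[occ] / counts[occ]
    return ScalarMap2D(
        grid=grid,
        values=values,
        counts=counts,
        metadata={
            "quantity": "order",
            "leaflet": leaflet,
            "species": ",".join(species_list),
            "frames": len(win),
        },
    )


def difference_map(a: ScalarMap2D, b: ScalarMap2D) -> ScalarMap2D:
    """Cellwise a - b; a cell is missing if it is missing in either input."""
    if not a.grid.matches(b.grid):
        raise GridMismatchError("maps are on different grids")
    both = a.occupied & b.occupied
    values = np.full_like(a.values, np.nan)
    values[both] = a.values[both] - b.values[both]
    counts = np.where(both, np.minimum(a.counts, b.counts), 0)
    meta = {
        "quantity": f"{a.metadata.get('quantity', 'a')}-{b.metadata.get('quantity', 'b')}",
        "a": dict(a.metadata),
        "b": dict(b.metadata),
    }
    return ScalarMap2D(grid=a.grid, values=values, counts=counts, metadata=meta)


def center_on_protein(
    traj: Trajectory, selection: str = "PROT"
) -> Trajectory:
    """Translate every frame so the protein's xy center sits at the box center.

    After the shift all molecules are wrapped back into the box as whole
    residues (by their mean xy), so lipids are never split by the move.
    The z coordinates are untouched.
    """
    frames = []
    for frame in traj:
        sel = frame.resnames == selection
        if not sel.any():
            raise ValueError(f"no beads with resname {selection!r} in frame")
        box = frame.box
        com = frame.positions[sel, :2].mean(axis=0)
        shift = np.array([box[0] / 2.0, box[1] / 2.0]) - com
        pos = frame.positions.copy()
        pos[:, :2] += shift
        # wrap whole residues
        _, inverse = np.unique(frame.resids, return_inverse=True)
        n_res = inverse.max() + 1
        for k in (0, 1):
            mean = np.zeros(n_res)
            cnt = np.zeros(n_res)
            np.add.at(mean, inverse, pos[:, k])
            np.add.at(cnt, inverse, 1.0)
            mean /= cnt
            offset = np.floor(mean / box[k]) * box[k]
            pos[:, k] -= offset[inverse]
        frames.append(
            Frame(pos, box.copy(), frame.names.copy(), frame.resnames.copy(),
                  frame.resids.copy(), frame.time)
        )
    return Trajectory(frames, traj.topology)
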