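"""Density maps, thickness maps, partial density profiles, interdigitation.

2D maps follow the one-reference-bead-per-lipid convention: a lipid is
counted where its reference phosphate falls, and per-species densities
are normalised by the total lipid count of the leaflet.  The partial
density profile histograms beads of configurable groups along z,
relative to the membrane center of mass of each frame, inside an xy
patch whose membership is re-evaluated every frame (strict inequalities
at the patch bounds).  Interdigitation metrics are read off the profile:
how far each leaflet's tails reach past the midplane, and the overlap
integral of the opposing tail densities.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, ScalarMap2D
from .io import Frame, LeafletAssignment, Trajectory, analysis_window, assign_leaflets
from .topology import LipidTopology

__all__ = [
    "density_map",
    "thickness_map",
    "GroupSelector",
    "standard_profile_groups",
    "DensityProfile",
    "partial_density_profile",
    "InterdigitationReport",
    "interdigitation",
    "DEFAULT_PATCH_BOUNDS",
]

# the worked example patch: 6 < x < 9 nm, 16 < y < 19 nm (a 3 x 3 nm patch)
DEFAULT_PATCH_BOUNDS = (6.0, 9.0, 16.0, 19.0)

DEFAULT_BEAD_MASS = 72.0  # amu; generic 4-to-1 CG bead


def _ref_positions(
    frame: Frame, topology: LipidTopology, species: str
) -> tuple[np.ndarray, np.ndarray]:
    sp = topology[species]
    mask = (frame.resnames == species) & (frame.names == sp.ref_bead)
    return frame.resids[mask], frame.positions[mask]


def density_map(
    traj: Trajectory,
    leaflet: str,
    species: str,
    topology: LipidTopology | None = None,
    grid: GridSpec | None = None,
    window: float = 0.5,
    normalized: bool = True,
    assignment: LeafletAssignment | None = None,
) -> ScalarMap2D:
    """Per-species 2D density of reference phosphates in one leaflet.

    The per-cell value is the mean (over window frames) count of
    reference beads, divided — when ``normalized`` — by the number of
    lipids of *all* species in the leaflet.  Every cell is observed every
    frame, so zero density is a value, not a missing cell; the count
    array holds the number of frames averaged.
    """
    topology = topology or traj.topology
    if topology is None:
        raise ValueError("a LipidTopology is required")
    win = analysis_window(traj, window)
    grid = grid or GridSpec.for_box(win[0].box)
    if assignment is None:
        assignment = assign_leaflets(win[0], topology)
    leaflet_ids = assignment.resids(leaflet)
    if len(leaflet_ids) == 0:
        raise ValueError(f"empty {leaflet} leaflet")

    acc = np.zeros((grid.n_x, grid.n_y))
    seen_any = False
    for frame in win:
        resids, pos = _ref_positions(frame, topology, species)
        sel = np.isin(resids, leaflet_ids)
        if sel.any():
            seen_any = True
            ix, iy = grid.bin_index(pos[sel, :2])
            np.add.at(acc, (ix, iy), 1.0)
    if not seen_any:
        raise ValueError(f"species {species!r} absent from the {leaflet} leaflet")
    values = acc / len(win)
    norm = float(len(leaflet_ids))
    if normalized:
        values = values / norm
    counts = np.full(values.shape, len(win), dtype=int)
    return ScalarMap2D(
        grid=grid,
        values=values,
        counts=counts,
        metadata={
            "quantity": "density",
            "leaflet": leaflet,
            "species": species,
            "frames": len(win),
            "n_leaflet_lipids": int(norm),
            "normalized": normalized,
        },
    )


def thickness_map(
    traj: Trajectory,
    topology: LipidTopology | None = None,
    grid: GridSpec | None = None,
    window: float = 0.5,
    assignment: LeafletAssignment | None = None,
) -> ScalarMap2D:
    """Phosphate-to-phosphate membrane thickness per cell.

    Per cell: mean upper reference-phosphate z minus mean lower
    reference-phosphate z over the window; missing wherever either
    leaflet contributed no lipid.
    """
    topology = topology or traj.topology
    if topology is None:
        raise ValueError("a LipidTopology is required")
    win = analysis_window(traj, window)
    grid = grid or GridSpec.for_box(win[0].box)
    if assignment is None:
        assignment = assign_leaflets(win[0], topology)  # raises if single leaflet

    shape = (grid.n_x, grid.n_y)
    z_sum = {"upper": np.zeros(shape), "lower": np.zeros(shape)}
    n = {"upper": np.zeros(shape, dtype=int), "lower": np.zeros(shape, dtype=int)}
    for frame in win:
        for s in topology.names():
            if not (frame.resnames == s).any():
                continue
            resids, pos = _ref_positions(frame, topology, s)
            for leaflet in ("upper", "lower"):
                sel = np.isin(resids, assignment.resids(leaflet))
                if sel.any():
                    ix, iy = grid.bin_index(pos[sel, :2])
                    np.add.at(z_sum[leaflet], (ix, iy), pos[sel, 2])
                    np.add.at(n[leaflet], (ix, iy), 1)
    both = (n["upper"] > 0) & (n["lower"] > 0)
    values = np.full(shape, np.nan)
    values[both] = (
        z_sum["upper"][both] / n["upper"][both]
        - z_sum["lower"][both] / n["lower"][both]
    )
    counts = np.where(both, np.minimum(n["upper"], n["lower"]), 0)
    return ScalarMap2D(
        grid=grid,
        values=values,
        counts=counts,
        metadata={"quantity": "thickness", "frames": len(win)},
    )


# --------------------------------------------------------------------------
# partial density profiles of dynamic subsets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSelector:
    """Which beads belong to a profile group.

    ``role`` is one of any | ref | tail | head (head includes linkers);
    ``leaflet`` restricts lipid species beads by the leaflet their lipid
    was assigned to.  Non-lipid residues (water, ions) match role "any"
    with their residue names listed explicitly.
    """

    resnames: tuple[str, ...] | None = None  # None = all lipid species
    role: str = "any"
    leaflet: str = "any"

    def mask(
        self, frame: Frame, topology: LipidTopology, assignment: LeafletAssignment
    ) -> np.ndarray:
        if self.resnames is None:
            names = topology.names()
        else:
            names = self.resnames
        sel = np.zeros(frame.n_beads, dtype=bool)
        for rn in names:
            m = frame.resnames == rn
            if not m.any():
                continue
            if rn in topology and self.role != "any":
                sp = topology[rn]
                if self.role == "ref":
                    wanted = (sp.ref_bead,)
                elif self.role == "tail":
                    wanted = sp.tail_bead_names
                elif self.role == "head":
                    wanted = sp.head_beads + sp.linker_beads
                else:
                    raise ValueError(f"unknown role {self.role!r}")
                m = m & np.isin(frame.names, wanted)
            sel |= m
        if self.leaflet != "any":
            sel &= np.isin(frame.resids, assignment.resids(self.leaflet))
        return sel


def standard_profile_groups() -> dict[str, GroupSelector]:
    """Water plus per-leaflet phosphate and tail groups."""
    return {
        "water": GroupSelector(resnames=("W", "WF"), role="any", leaflet="any"),
        "upper_phosphates": GroupSelector(role="ref", leaflet="upper"),
        "lower_phosphates": GroupSelector(role="ref", leaflet="lower"),
        "upper_tails": GroupSelector(role="tail", leaflet="upper"),
        "lower_tails": GroupSelector(role="tail", leaflet="lower"),
    }


@dataclass
class DensityProfile:
    """z-resolved partial densities of bead groups inside an xy patch.

    ``z`` bin centers are relative to the per-frame membrane center of
    mass.  ``count_density`` is beads per nm^3; ``mass_density`` scales
    it by a per-bead mass (amu per nm^3).  The integral of count density
    times bin volume over z returns the mean bead count of the group in
    the patch.
    """

    z_centers: np.ndarray
    bin_width: float
    patch_bounds: tuple[float, float, float, float]
    frames_used: int
    count_density: dict[str, np.ndarray] = field(default_factory=dict)
    mass_density: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def patch_area(self) -> float:
        x0, x1, y0, y1 = self.patch_bounds
        return (x1 - x0) * (y1 - y0)

    def mean_count(self, group: str) -> float:
        return float(
            np.sum(self.count_density[group]) * self.patch_area * self.bin_width
        )

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for g in self.count_density:
            frames.append(
                pd.DataFrame(
                    {
                        "z": self.z_centers,
                        "group": g,
                        "count_density": self.count_density[g],
                        "mass_density": self.mass_density[g],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path, header_comments: dict | None = None) -> None:
        buf = _io.StringIO()
        meta = {
            "patch_bounds": self.patch_bounds,
            "bin_width": self.bin_width,
            "frames_used": self.frames_used,
        }
        if header_comments:
            meta.update(header_comments)
        for k, v in sorted(meta.items()):
            buf.write(f"# {k}={v}\n")
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def partial_density_profile(
    traj: Trajectory,
    patch_bounds: tuple[float, float, float, float] = DEFAULT_PATCH_BOUNDS,
    groups: dict[str, GroupSelector] | None = None,
    topology: LipidTopology | None = None,
    bin_width: float = 0.1,
    window: float = 0.125,
    mass_table: dict[str, float] | None = None,
    assignment: LeafletAssignment | None = None,
) -> DensityProfile:
    """Partial density profile of a dynamic subset of beads.

    Per frame, beads with xy strictly inside the patch (membership
    re-evaluated every frame — the subset may change size over time) are
    histogrammed in z relative to that frame's membrane center of mass;
    histograms are averaged over the trailing window (default the last
    1/8 of the frames) and converted to densities with patch area x bin
    width.  Center of mass uses unit bead masses by default; pass
    ``mass_table`` (bead name -> amu) to weight it and the mass-density
    variant.
    """
    topology = topology or traj.topology
    if topology is None:
        raise ValueError("a LipidTopology is required")
    x0, x1, y0, y1 = patch_bounds
    if x1 <= x0 or y1 <= y0:
        raise ValueError("zero-area patch")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    box = traj[0].box
    if x1 > box[0] or y1 > box[1] or x0 < 0 or y0 < 0:
        raise ValueError("patch extends outside the box")
    groups = groups or standard_profile_groups()
    win = analysis_window(traj, window)
    if assignment is None:
        assignment = assign_leaflets(win[0], topology)

    # z range spans a full box length either side of the COM so that no
    # bead ever falls off the histogram (conservation holds exactly)
    half = box[2]
    n_bins = int(np.ceil(2.0 * half / bin_width))
    edges = -half + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc = {g: np.zeros(n_bins) for g in groups}
    acc_mass = {g: np.zeros(n_bins) for g in groups}

    lipid_mask0 = np.isin(
        traj[0].resnames, np.array(topology.names(), dtype=object)
    )
    for frame in win:
        pos = frame.positions
        xy = np.mod(pos[:, :2], box[:2])
        z = pos[:, 2]
        # COM weights: unit masses unless a mass table is supplied
        com_w = (
            np.ones(lipid_mask0.sum())
            if mass_table is None
            else np.array(
                [mass_table.get(str(n), DEFAULT_BEAD_MASS) for n in frame.names[lipid_mask0]]
            )
        )
        com_z = float(np.average(z[lipid_mask0], weights=com_w))
        masses = (
            np.full(frame.n_beads, DEFAULT_BEAD_MASS)
            if mass_table is None
            else np.array([mass_table.get(str(n), DEFAULT_BEAD_MASS) for n in frame.names])
        )
        in_patch = (xy[:, 0] > x0) & (xy[:, 0] < x1) & (xy[:, 1] > y0) & (xy[:, 1] < y1)
        rel_z = z - com_z
        for g, selector in groups.items():
            sel = selector.mask(frame, topology, assignment) & in_patch
            if sel.any():
                hist, _ = np.histogram(rel_z[sel], bins=edges)
                acc[g] += hist
                mhist, _ = np.histogram(rel_z[sel], bins=edges, weights=masses[sel])
                acc_mass[g] += mhist
    area = (x1 - x0) * (y1 - y0)
    bin_volume = area * bin_width
    count_density = {g: acc[g] / len(win) / bin_volume for g in groups}
    mass_density = {g: acc_mass[g] / len(win) / bin_volume for g in groups}
    return DensityProfile(
        z_centers=centers,
        bin_width=bin_width,
        patch_bounds=tuple(patch_bounds),
        frames_used=len(win),
        count_density=count_density,
        mass_density=mass_density,
    )


# --------------------------------------------------------------------------
# interdigitation metrics
# --------------------------------------------------------------------------


@dataclass
class InterdigitationReport:
    """How far each leaflet's tails reach past the midplane.

    ``asymmetry`` = lower-into-upper minus upper-into-lower penetration
    (nm); positive when the lower leaflet's tails reach further up than
    the upper leaflet's tails reach down.  ``overlap`` is the integral of
    min(upper-tail, lower-tail density) over z, in beads per nm^2.
    """

    upper_into_lower: float
    lower_into_upper: float
    overlap: float
    asymmetry: float
    midplane_z: float
    threshold: float

    def to_dict(self) -> dict:
        return {
            "upper_into_lower_nm": self.upper_into_lower,
            "lower_into_upper_nm": self.lower_into_upper,
            "overlap_beads_per_nm2": self.overlap,
            "asymmetry_nm": self.asymmetry,
            "midplane_z_nm": self.midplane_z,
            "threshold": self.threshold,
        }


def _phosphate_midplane(profile: DensityProfile) -> float:
    """z where upper and lower phosphate densities cross, else 0 (COM)."""
    if (
        "upper_phosphates" not in profile.count_density
        or "lower_phosphates" not in profile.count_density
    ):
        return 0.0
    up = profile.count_density["upper_phosphates"]
    lo = profile.count_density["lower_phosphates"]
    if up.sum() == 0 or lo.sum() == 0:
        return 0.0
    z = profile.z_centers
    i_lo, i_up = int(np.argmax(lo)), int(np.argmax(up))
    if i_lo >= i_up:
        return 0.0
    # equal-density locus between the two phosphate peaks: collect exact
    # zeros of (up - lo) plus interpolated sign crossings; when the peaks
    # are well separated the locus is a plateau, so use its center
    diff = up - lo
    candidates: list[float] = []
    for i in range(i_lo, i_up + 1):
        if diff[i] == 0.0:
            candidates.append(float(z[i]))
        if i < i_up and diff[i] * diff[i + 1] < 0:
            t = -diff[i] / (diff[i + 1] - diff[i])
            candidates.append(float(z[i] + t * (z[i + 1] - z[i])))
    if not candidates:
        return 0.0
    return float(0.5 * (min(candidates) + max(candidates)))


def interdigitation(
    profile: DensityProfile, threshold: float = 0.05
) -> InterdigitationReport:
    """Interdigitation metrics from a partial density profile.

    Penetration depth: the distance past the midplane at which a
    leaflet's tail density falls below ``threshold`` x its own peak.
    The midplane is the phosphate-density crossing, falling back to the
    membrane center of mass (z = 0 of the profile).
    """
    for g in ("upper_tails", "lower_tails"):
        if g not in profile.count_density:
            raise ValueError(f"profile lacks group {g!r}")
    up = profile.count_density["upper_tails"]
    lo = profile.count_density["lower_tails"]
    if up.sum() == 0 or lo.sum() == 0:
        raise ValueError("all-zero tail densities")
    z = profile.z_centers
    mid = _phosphate_midplane(profile)

    def depth(density: np.ndarray, direction: int) -> float:
        # direction -1: upper tails reaching below mid; +1: lower reaching above
        thr = threshold * float(density.max())
        if direction < 0:
            sel = (z < mid) & (density >= thr)
            return float(mid - z[sel].min()) if sel.any() else 0.0
        sel = (z > mid) & (density >= thr)
        return float(z[sel].max() - mid) if sel.any() else 0.0

    upper_into_lower = depth(up, -1)
    lower_into_upper = depth(lo, +1)
    overlap = float(np.sum(np.minimum(up, lo)) * profile.bin_width)
    return InterdigitationReport(
        upper_into_lower=upper_into_lower,
        lower_into_upper=lower_into_upper,
        overlap=overlap,
        asymmetry=lower_into_upper - upper_into_lower,
        midplane_z=mid,
        threshold=threshold,
    )
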