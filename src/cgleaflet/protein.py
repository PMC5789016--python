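"""Protein insertion into a membrane: concave hull, clash removal, placement.

The insertion rule: a lipid overlaps the protein if any of its beads
projects into the protein's 2D concave hull in the xy plane, or lies
within a clash distance (default 0.1 nm, 3D, periodic) of any protein
bead.  The protein is placed stochastically inside a 2D disk (default
radius 3 nm) until the whole-membrane lipid composition change stays
below a bound (default 0.20 percentage points).

The concave hull is formalised as the alpha shape: the union of Delaunay
triangles whose circumradius is at most ``alpha`` (nm).  As alpha grows
the shape converges to the convex hull.  Interior holes of the union are
filled — for clash removal the hull means everything enclosed by the
outer boundary, lumen included.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .io import Frame, assign_leaflets
from .topology import LipidTopology

__all__ = [
    "ProteinModel",
    "InsertionResult",
    "AlphaShapeError",
    "InsertionError",
    "concave_hull_2d",
    "find_overlaps",
    "insert_protein",
]


class AlphaShapeError(ValueError):
    """Alpha shape is empty, disconnected, or the points are degenerate."""


class InsertionError(RuntimeError):
    """Placement attempts exhausted; carries the best attempt found."""

    def __init__(self, message: str, best: "InsertionResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class ProteinModel:
    """Bead cloud of a (coarse-grained) protein, axis along z by convention."""

    positions: np.ndarray  # (n, 3) nm
    names: np.ndarray
    principal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        if len(self.positions) < 4:
            raise ValueError("a protein model needs at least 4 beads")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite protein coordinates")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def translated(self, shift) -> "ProteinModel":
        return ProteinModel(
            self.positions + np.asarray(shift, dtype=float),
            self.names.copy(),
            self.principal_axis.copy(),
        )

    def z_extent(self) -> float:
        return float(self.positions[:, 2].max() - self.positions[:, 2].min())

    def xy_extent(self) -> float:
        xy = self.positions[:, :2]
        return float(max(xy[:, 0].max() - xy[:, 0].min(), xy[:, 1].max() - xy[:, 1].min()))


def concave_hull_2d(points: np.ndarray, alpha: float) -> Polygon:
    """Alpha-shape boundary polygon of a 2D point set.

    Keeps Delaunay triangles with circumradius <= alpha and returns the
    (hole-filled) union.  Raises AlphaShapeError if the points are
    collinear or if alpha is too small to produce one connected region;
    a disconnected shape is never silently reduced to a component.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        raise AlphaShapeError("need at least 3 points")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise AlphaShapeError(f"degenerate point set (collinear?): {exc}") from exc

    a, b, c = (pts[tri.simplices[:, k]] for k in range(3))
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)
    keep = tri.simplices[circumradius <= alpha]
    if len(keep) == 0:
        raise AlphaShapeError(f"alpha={alpha} keeps no triangle; increase alpha")
    union = unary_union([Polygon(pts[s]) for s in keep])
    if union.geom_type == "MultiPolygon":
        raise AlphaShapeError(
            f"alpha={alpha} yields {len(union.geoms)} disconnected regions; increase alpha"
        )
    if union.is_empty or union.geom_type != "Polygon":
        raise AlphaShapeError("alpha shape degenerated to a non-areal geometry")
    return Polygon(union.exterior)


def _lipid_bead_mask(frame: Frame, topology: LipidTopology) -> np.ndarray:
    mask = np.zeros(frame.n_beads, dtype=bool)
    for name in topology.names():
        mask |= frame.resnames == name
    return mask


def find_overlaps(
    frame: Frame,
    topology: LipidTopology,
    protein: ProteinModel,
    hull: Polygon,
    min_dist: float = 0.1,
) -> set[int]:
    """Lipid resids overlapping a placed protein.

    A lipid overlaps iff any of its beads projects (xy, periodic images
    included) inside the concave hull, or any of its beads is within
    ``min_dist`` (3D Euclidean, periodic) of any protein bead.
    """
    if protein.n_beads == 0:
        raise ValueError("empty protein")
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    box = frame.box
    mask = _lipid_bead_mask(frame, topology)
    bead_pos = np.mod(frame.positions[mask], box)
    bead_resids = frame.resids[mask]

    overl = np.zeros(len(bead_pos), dtype=bool)
    # clash distance, periodic in all three dimensions
    if min_dist > 0:
        tree = cKDTree(np.mod(protein.positions, box), boxsize=box)
        hits = tree.query_ball_point(bead_pos, r=min_dist)
        overl |= np.array([len(h) > 0 for h in hits])

    shapely.prepare(hull)
    for sx in (-box[0], 0.0, box[0]):
        for sy in (-box[1], 0.0, box[1]):
            overl |= shapely.contains_xy(hull, bead_pos[:, 0] + sx, bead_pos[:, 1] + sy)
    return set(int(r) for r in np.unique(bead_resids[overl]))


def _species_counts(frame: Frame, topology: LipidTopology) -> dict[str, int]:
    counts: dict[str, int] = {}
    mask = _lipid_bead_mask(frame, topology)
    resids = frame.resids[mask]
    resnames = frame.resnames[mask]
    _, first = np.unique(resids, return_index=True)
    for rn in resnames[first]:
        counts[rn] = counts.get(rn, 0) + 1
    return counts


def _fractions(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()} if total else {}


@dataclass
class InsertionResult:
    """Outcome of one (accepted or best-effort) protein placement."""

    center: tuple[float, float]
    removed_upper: tuple[int, ...]
    removed_lower: tuple[int, ...]
    composition_before: dict[str, float]
    composition_after: dict[str, float]
    max_change_pp: float  # max over species of |delta mole fraction|, percentage points
    attempts: int
    seed: int
    accepted: bool
    frame: Frame | None = None  # membrane minus removed lipids plus protein

    @property
    def removed(self) -> tuple[int, ...]:
        return tuple(sorted(self.removed_upper + self.removed_lower))

    def to_json(self, path=None) -> str:
        doc = {
            "center": list(self.center),
            "removed_upper": list(self.removed_upper),
            "removed_lower": list(self.removed_lower),
            "composition_before": self.composition_before,
            "composition_after": self.composition_after,
            "max_change_pp": self.max_change_pp,
            "attempts": self.attempts,
            "seed": self.seed,
            "accepted": self.accepted,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def insert_protein(
    frame: Frame,
    topology: LipidTopology,
    protein: ProteinModel,
    disk_center: tuple[float, float] | None = None,
    disk_radius: float = 3.0,
    max_change: float = 0.20,
    max_attempts: int = 500,
    seed: int = 0,
    alpha: float = 0.6,
    min_dist: float = 0.1,
    scope: str = "membrane",
) -> InsertionResult:
    """Place a transmembrane protein, removing overlapping lipids.

    Repeats: sample a uniform point in the placement disk (rejection
    sampling), put the protein there with its z-center on the bilayer
    midplane, remove overlapping lipids, and measure the change in lipid
    composition — until the maximum per-species mole-fraction change is
    below ``max_change`` percentage points (default 0.20) or attempts run
    out.  ``scope`` is "membrane" (whole-membrane fractions, default) or
    "leaflet" (max over species within each leaflet).  Deterministic for
    a fixed seed.
    """
    if disk_radius <= 0:
        raise ValueError("disk radius must be positive")
    box = frame.box
    center = (
        np.array([box[0] / 2.0, box[1] / 2.0])
        if disk_center is None
        else np.asarray(disk_center, dtype=float)
    )
    if not (
        disk_radius <= center[0] <= box[0] - disk_radius
        and disk_radius <= center[1] <= box[1] - disk_radius
    ):
        raise ValueError("placement disk extends outside the box")
    if protein.xy_extent() > min(box[0], box[1]):
        raise ValueError("protein larger than the membrane patch")
    if scope not in ("membrane", "leaflet"):
        raise ValueError("scope must be 'membrane' or 'leaflet'")

    assignment = assign_leaflets(frame, topology)
    midplane = assignment.midplane_z
    upper_set = set(assignment.upper.tolist())
    counts_before = _species_counts(frame, topology)
    frac_before = _fractions(counts_before)
    resid_species = _resid_species(frame, topology)

    base_hull = concave_hull_2d(protein.positions[:, :2], alpha)
    rng = np.random.default_rng(seed)

    best: InsertionResult | None = None
    for attempt in range(1, max_attempts + 1):
        # uniform point in the disk by rejection sampling
        while True:
            xy = rng.uniform(-disk_radius, disk_radius, size=2)
            if xy @ xy <= disk_radius * disk_radius:
                break
        place = np.array([center[0] + xy[0], center[1] + xy[1], midplane])
        placed = protein.translated(place - np.array([0.0, 0.0, 0.0]))
        hull = shapely.affinity.translate(base_hull, xoff=place[0], yoff=place[1])
        removed = find_overlaps(frame, topology, placed, hull, min_dist)

        counts_after = dict(counts_before)
        for rid in removed:
            counts_after[resid_species[rid]] -= 1
        if scope == "membrane":
            frac_after = _fractions(counts_after)
            change = max(
                abs(frac_after.get(s, 0.0) - frac_before.get(s, 0.0))
                for s in set(frac_before) | set(frac_after)
            )
        else:
            change = _leaflet_change(
                frame, topology, assignment, removed, resid_species
            )
        change_pp = 100.0 * change

        result = InsertionResult(
            center=(float(place[0]), float(place[1])),
            removed_upper=tuple(sorted(r for r in removed if r in upper_set)),
            removed_lower=tuple(sorted(r for r in removed if r not in upper_set)),
            composition_before=frac_before,
            composition_after=_fractions(counts_after),
            max_change_pp=change_pp,
            attempts=attempt,
            seed=seed,
            accepted=change_pp < max_change,
        )
        if best is None or result.max_change_pp < best.max_change_pp:
            best = result
        if result.accepted:
            result.frame = _assemble(frame, removed, placed)
            return result

    raise InsertionError(
        f"no placement below {max_change} pp in {max_attempts} attempts "
        f"(best: {best.max_change_pp:.4f} pp)",
        best=best,
    )


def _resid_species(frame: Frame, topology: LipidTopology) -> dict[int, str]:
    mask = _lipid_bead_mask(frame, topology)
    resids = frame.resids[mask]
    resnames = frame.resnames[mask]
    _, first = np.unique(resids, return_index=True)
    return {int(resids[i]): str(resnames[i]) for i in first}


def _leaflet_change(frame, topology, assignment, removed, resid_species) -> float:
    worst = 0.0
    for leaflet in ("upper", "lower"):
        ids = assignment.resids(leaflet)
        counts: dict[str, int] = {}
        for rid in ids:
            counts[resid_species[int(rid)]] = counts.get(resid_species[int(rid)], 0) + 1
        before = _fractions(counts)
        after_counts = dict(counts)
        for rid in removed:
            if (leaflet == "upper") == (rid in set(assignment.upper.tolist())):
                after_counts[resid_species[rid]] -= 1
        after = _fractions(after_counts)
        for s in set(before) | set(after):
            worst = max(worst, abs(after.get(s, 0.0) - before.get(s, 0.0)))
    return worst


def _assemble(frame: Frame, removed: set[int], placed: ProteinModel) -> Frame:
    keep = ~np.isin(frame.resids, list(removed))
    resid_prot = int(frame.resids.max()) + 1
    n_p = placed.n_beads
    return Frame(
        positions=np.concatenate([frame.positions[keep], placed.positions]),
        box=frame.box.copy(),
        names=np.concatenate([frame.names[keep], placed.names]),
        resnames=np.concatenate(
            [frame.resnames[keep], np.repeat(np.array(["PROT"], dtype=object), n_p)]
        ),
        resids=np.concatenate([frame.resids[keep], np.full(n_p, resid_prot)]),
        time=frame.time,
    )
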