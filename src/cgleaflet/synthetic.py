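"""Synthetic coarse-grained membranes with planted, exactly known structure.

Real CG membranes come out of force-field simulations; recovering their
properties gives nothing to check an estimator against.  This generator
instead *plants* the structure the analyses are supposed to find:

* a two-leaflet planar bilayer on a jittered lattice (upper leaflet
  LPS-like by default, lower a 90/5/5 POPE/POPG/cardiolipin mixture);
* a target tail order field P2(x, y) per leaflet, realised exactly by
  tilting every tail bond to the analytic angle
  ``theta = arccos(sqrt((2 P2 + 1) / 3))`` with uniform random azimuth,
  so each bond's second-rank order equals the target to machine precision;
* headgroup voids (depleted upper-leaflet packing, locally thinned
  membrane) and species cluster regions (e.g. cardiolipin enrichment);
* per-leaflet tail interdigitation depths past the midplane;
* a per-leaflet lateral mobility scale, emulating the order-of-magnitude
  slowdown of a cation-cross-linked LPS layer relative to phospholipids;
* water with a configurable antifreeze particle fraction, plus
  neutralising ions.

Species mole fractions are realised by largest-remainder rounding, so the
generated composition never deviates from the requested one by a full
lipid.  Identical configuration + seed gives bit-identical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Frame, Trajectory
from .protein import ProteinModel
from .topology import LipidTopology, default_topology

__all__ = [
    "GeneratorConfig",
    "GeneratorConfigError",
    "PlantedTruth",
    "generate_membrane",
    "generate_solvent",
    "generate_system",
    "generate_protein_barrel",
    "ompa_like_barrel",
    "ompf_monomer_like_barrel",
    "largest_remainder_counts",
    "tilt_angle_for_p2",
]

OrderField = float | Callable[[np.ndarray, np.ndarray], np.ndarray]

# geometric constants of the generated lipids (nm)
BOND_LENGTH = 0.47
HEAD_SPACING = 0.30
LINKER_DROP = 0.30
TAIL_RING_RADIUS = 0.15


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Everything the membrane generator needs; see module docstring.

    ``order_field_*`` may be a constant P2 in [-0.5, 1] or a vectorised
    callable ``f(x, y) -> P2`` evaluated at lipid positions every frame.
    ``void_regions`` is a list of ``((x, y), radius)``; ``cluster_spec``
    maps a species name to ``[((x, y), radius, enrichment >= 1), ...]``.
    """

    box: tuple[float, float, float] = (23.0, 23.0, 15.0)
    composition_upper: dict[str, float] = dc_field(default_factory=lambda: {"LPS": 1.0})
    composition_lower: dict[str, float] = dc_field(
        default_factory=lambda: {"POPE": 0.90, "POPG": 0.05, "CDL": 0.05}
    )
    lipids_per_leaflet: int = 400
    order_field_upper: OrderField = 0.4
    order_field_lower: OrderField = 0.4
    void_regions: list[tuple[tuple[float, float], float]] = dc_field(default_factory=list)
    void_depletion: float = 0.7
    void_thinning: float = 0.25
    cluster_spec: dict[str, list[tuple[tuple[float, float], float, float]]] = dc_field(
        default_factory=dict
    )
    interdigitation_upper: float = 0.3
    interdigitation_lower: float = 0.3
    thickness: float = 4.0  # reference-phosphate to reference-phosphate, nm
    mobility_sigma_upper: float = 0.05
    mobility_sigma_lower: float = 0.05
    n_frames: int = 1
    dt_ps: float = 1000.0
    n_water: int = 8000
    antifreeze_fraction: float = 0.02
    lps_n_tails: int = 6
    lps_n_head: int = 8
    tail_beads: int = 4
    lattice_jitter: float = 0.08  # fraction of lattice spacing
    seed: int = 0

    def validate(self) -> None:
        if any(b <= 0 for b in self.box):
            raise GeneratorConfigError("box lengths must be positive")
        for label, comp in (
            ("upper", self.composition_upper),
            ("lower", self.composition_lower),
        ):
            if not comp:
                raise GeneratorConfigError(f"{label} leaflet composition is empty")
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise GeneratorConfigError(
                    f"{label} leaflet mole fractions sum to {total}, not 1"
                )
            if any(f < 0 for f in comp.values()):
                raise GeneratorConfigError("negative mole fraction")
        if self.lipids_per_leaflet < 1:
            raise GeneratorConfigError("need at least one lipid per leaflet")
        for f in (self.order_field_upper, self.order_field_lower):
            if not callable(f):
                _check_p2(np.asarray(float(f)))
        for (cx, cy), r in self.void_regions:
            self._check_region(cx, cy, r, "void")
        for sp, regions in self.cluster_spec.items():
            for (cx, cy), r, enrich in regions:
                self._check_region(cx, cy, r, f"cluster[{sp}]")
                if enrich < 1:
                    raise GeneratorConfigError("cluster enrichment must be >= 1")
        if self.mobility_sigma_upper < 0 or self.mobility_sigma_lower < 0:
            raise GeneratorConfigError("mobility sigmas must be >= 0")
        if self.interdigitation_upper < 0 or self.interdigitation_lower < 0:
            raise GeneratorConfigError("interdigitation depths must be >= 0")
        if not 0 <= self.void_depletion <= 1 or not 0 <= self.void_thinning < 1:
            raise GeneratorConfigError("void depletion/thinning must lie in [0, 1]")
        if self.n_frames < 1:
            raise GeneratorConfigError("n_frames must be >= 1")
        if self.n_water < 0 or not 0 <= self.antifreeze_fraction <= 1:
            raise GeneratorConfigError("invalid solvent settings")

    def _check_region(self, cx: float, cy: float, r: float, label: str) -> None:
        lx, ly = self.box[0], self.box[1]
        if r <= 0:
            raise GeneratorConfigError(f"{label} radius must be positive")
        if not (0 <= cx <= lx and 0 <= cy <= ly):
            raise GeneratorConfigError(f"{label} center outside the box")
        if 2 * r > min(lx, ly):
            raise GeneratorConfigError(f"{label} region exceeds the box")

    def topology(self) -> LipidTopology:
        return default_topology(self.lps_n_tails, self.lps_n_head, self.tail_beads)


@dataclass
class PlantedTruth:
    """Ground truth of a generated membrane, one record per lipid.

    ``positions``/``p2_target`` have shape (n_frames, n_lipids, ...) and
    track every lipid through the trajectory, so recovery tests can
    compare any estimator against what was actually planted.
    """

    lipid_ids: np.ndarray  # (n,) resids
    species: np.ndarray  # (n,) str
    leaflet: np.ndarray  # (n,) "upper" | "lower"
    positions: np.ndarray  # (n_frames, n, 2) nm, wrapped lipid centers
    p2_target: np.ndarray  # (n_frames, n)
    cluster_member: np.ndarray  # (n,) bool, lipid born inside a cluster region
    void_member: np.ndarray  # (n,) bool

    def leaflet_ids(self, leaflet: str) -> np.ndarray:
        return self.lipid_ids[self.leaflet == leaflet]

    def to_dataframe(self) -> pd.DataFrame:
        n_frames, n = self.p2_target.shape
        rows = {
            "frame": np.repeat(np.arange(n_frames), n),
            "lipid_id": np.tile(self.lipid_ids, n_frames),
            "species": np.tile(self.species, n_frames),
            "leaflet": np.tile(self.leaflet, n_frames),
            "x": self.positions[:, :, 0].ravel(),
            "y": self.positions[:, :, 1].ravel(),
            "p2_target": self.p2_target.ravel(),
            "cluster_member": np.tile(self.cluster_member, n_frames),
            "void_member": np.tile(self.void_member, n_frames),
        }
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# --------------------------------------------------------------------------
# small pure helpers
# --------------------------------------------------------------------------


def tilt_angle_for_p2(p2: np.ndarray) -> np.ndarray:
    """Polar angle whose fixed-cone orientation has bond order exactly p2."""
    p2 = np.asarray(p2, dtype=float)
    _check_p2(p2)
    return np.arccos(np.sqrt((2.0 * p2 + 1.0) / 3.0))


def _check_p2(p2: np.ndarray) -> None:
    if np.any(p2 < -0.5 - 1e-12) or np.any(p2 > 1.0 + 1e-12):
        raise GeneratorConfigError("planted P2 targets must lie in [-0.5, 1]")


def largest_remainder_counts(composition: Mapping[str, float], n: int) -> dict[str, int]:
    """Integer species counts realising mole fractions by largest remainder.

    Ties in the fractional remainders are broken by species name order,
    making the rounding deterministic.
    """
    names = sorted(composition)
    ideal = {s: composition[s] * n for s in names}
    counts = {s: int(math.floor(ideal[s])) for s in names}
    short = n - sum(counts.values())
    by_remainder = sorted(names, key=lambda s: (-(ideal[s] - counts[s]), s))
    for s in by_remainder[:short]:
        counts[s] += 1
    return counts


def _min_image_dist2(xy: np.ndarray, center: Sequence[float], box: Sequence[float]) -> np.ndarray:
    d = xy - np.asarray(center, dtype=float)
    for k in (0, 1):
        d[:, k] -= box[k] * np.round(d[:, k] / box[k])
    return np.einsum("ij,ij->i", d, d)


def _in_regions(xy: np.ndarray, regions, box) -> np.ndarray:
    hit = np.zeros(len(xy), dtype=bool)
    for (cx, cy), r, *_ in regions:
        hit |= _min_image_dist2(xy, (cx, cy), box) <= r * r
    return hit


def _eval_field(f: OrderField, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if callable(f):
        p2 = np.asarray(f(x, y), dtype=float)
        p2 = np.broadcast_to(p2, x.shape).copy()
    else:
        p2 = np.full(x.shape, float(f))
    _check_p2(p2)
    return p2


# --------------------------------------------------------------------------
# membrane generation
# --------------------------------------------------------------------------


@dataclass
class _LeafletPlan:
    xy0: np.ndarray  # (n, 2) initial lipid centers
    species: np.ndarray  # (n,) str
    cluster_member: np.ndarray
    void_member: np.ndarray


def _plan_leaflet(cfg: GeneratorConfig, leaflet: str, rng: np.random.Generator) -> _LeafletPlan:
    n = cfg.lipids_per_leaflet
    lx, ly = cfg.box[0], cfg.box[1]
    # voids deplete by down-weighting candidate sites, which only bites
    # if there are surplus candidates to choose from
    deplete = leaflet == "upper" and bool(cfg.void_regions) and cfg.void_depletion > 0
    m = int(math.ceil(math.sqrt(1.6 * n if deplete else n)))
    sx, sy = lx / m, ly / m
    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    sites = np.column_stack(
        [(gx.ravel() + 0.5) * sx, (gy.ravel() + 0.5) * sy]
    ).astype(float)
    sites += rng.normal(0.0, cfg.lattice_jitter * min(sx, sy), size=sites.shape)
    sites[:, 0] %= lx
    sites[:, 1] %= ly

    weights = np.ones(len(sites))
    if leaflet == "upper" and cfg.void_regions:
        in_void = _in_regions(sites, [(c, r) for c, r in cfg.void_regions], cfg.box)
        weights[in_void] *= 1.0 - cfg.void_depletion
    if weights.sum() <= 0:
        raise GeneratorConfigError("void depletion removed every candidate site")
    chosen = rng.choice(len(sites), size=n, replace=False, p=weights / weights.sum())
    xy = sites[chosen]

    comp = cfg.composition_upper if leaflet == "upper" else cfg.composition_lower
    counts = largest_remainder_counts(comp, n)
    species = np.empty(n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    clustered = [s for s in sorted(counts) if counts[s] and s in cfg.cluster_spec]
    plain = [s for s in sorted(counts) if counts[s] and s not in cfg.cluster_spec]
    pinned = np.zeros(n, dtype=bool)
    for s in clustered:
        idx = np.flatnonzero(unassigned)
        w = np.ones(len(idx))
        for (cx, cy), r, enrich in cfg.cluster_spec[s]:
            inside = _min_image_dist2(xy[idx], (cx, cy), cfg.box) <= r * r
            w[inside] *= enrich
        # The enrichment factor is the *stationary* density ratio of the
        # generated dynamics: cluster members stay pinned at their
        # anchors while the rest of the species random-walks (uniform in
        # steady state).  Solving ratio_w = w for the pinned count per
        # weight stratum gives n_pin,w = (w - 1) a_w n_free, with a_w the
        # stratum's area share; counts realized by largest remainder.
        strata = [wv for wv in np.unique(w) if wv > 1.0]
        a = {wv: float(np.sum(w == wv)) / len(w) for wv in strata}
        denom = 1.0 + sum((wv - 1.0) * a[wv] for wv in strata)
        shares = {f"{wv:.12g}": (wv - 1.0) * a[wv] / denom for wv in strata}
        shares["__free__"] = 1.0 / denom
        per_stratum = largest_remainder_counts(shares, counts[s])
        taken: list[np.ndarray] = []
        for wv in strata:
            pool = np.flatnonzero(w == wv)
            k_take = min(per_stratum[f"{wv:.12g}"], len(pool))
            chosen = rng.choice(pool, size=k_take, replace=False)
            taken.append(chosen)
            pinned[idx[chosen]] = True
        n_free = counts[s] - sum(len(t) for t in taken)
        free_pool = np.setdiff1d(np.arange(len(idx)), np.concatenate(taken) if taken else [])
        taken.append(rng.choice(free_pool, size=n_free, replace=False))
        take = np.concatenate(taken)
        species[idx[take]] = s
        unassigned[idx[take]] = False
    idx = rng.permutation(np.flatnonzero(unassigned))
    start = 0
    for s in plain:
        species[idx[start : start + counts[s]]] = s
        start += counts[s]

    # cluster members are the pinned lipids (trapped in their region);
    # free lipids of the same species are background, wherever they start
    cluster_member = pinned
    void_member = (
        _in_regions(xy, [(c, r) for c, r in cfg.void_regions], cfg.box)
        if cfg.void_regions
        else np.zeros(n, dtype=bool)
    )
    return _LeafletPlan(xy, species, cluster_member, void_member)


def _thickness_factor(cfg: GeneratorConfig, xy: np.ndarray) -> np.ndarray:
    """Local thinning near voids: 1 away from voids, (1 - thinning) inside.

    The thinned zone extends to 1.5x the void radius so that the lipids
    surviving depletion (mostly the annulus around the void) show it.
    Both leaflets' phosphates move toward the midplane symmetrically.
    """
    factor = np.ones(len(xy))
    for (cx, cy), r in cfg.void_regions:
        inside = _min_image_dist2(xy.copy(), (cx, cy), cfg.box) <= (1.5 * r) ** 2
        factor[inside] = 1.0 - cfg.void_thinning
    return factor


def _build_lipid_beads(
    cfg: GeneratorConfig,
    topo: LipidTopology,
    plan: _LeafletPlan,
    xy: np.ndarray,
    leaflet: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bead coordinates for one leaflet in one frame (midplane at z = 0).

    Returns (positions, names, resnames, per-bead lipid index).  Bond
    directions use the exact analytic tilt; tail terminal beads sit at
    the planted interdigitation depth past the midplane.
    """
    sgn = 1.0 if leaflet == "upper" else -1.0
    depth = cfg.interdigitation_upper if leaflet == "upper" else cfg.interdigitation_lower
    field = cfg.order_field_upper if leaflet == "upper" else cfg.order_field_lower
    p2 = _eval_field(field, xy[:, 0], xy[:, 1])
    theta = tilt_angle_for_p2(p2)
    zref = 0.5 * cfg.thickness * _thickness_factor(cfg, xy)

    pos_chunks: list[np.ndarray] = []
    name_chunks: list[np.ndarray] = []
    res_chunks: list[np.ndarray] = []
    lip_chunks: list[np.ndarray] = []
    for sname in sorted(set(plan.species.tolist())):
        sp = topo[sname]
        sel = np.flatnonzero(plan.species == sname)
        k = len(sel)
        cx, cy = xy[sel, 0], xy[sel, 1]
        th, zr = theta[sel], zref[sel]
        bead_pos: list[np.ndarray] = []
        bead_names: list[str] = []
        for j, bname in enumerate(sp.head_beads):
            z = sgn * (zr + HEAD_SPACING * (j + 1))
            bead_pos.append(np.column_stack([cx, cy, z]))
            bead_names.append(bname)
        bead_pos.append(np.column_stack([cx, cy, sgn * zr]))
        bead_names.append(sp.ref_bead)
        n_link = len(sp.linker_beads)
        for j, bname in enumerate(sp.linker_beads):
            dx = 0.12 * (j - (n_link - 1) / 2.0)
            z = sgn * (zr - LINKER_DROP)
            bead_pos.append(np.column_stack([cx + dx, cy, z]))
            bead_names.append(bname)
        # Tails run from just below the glycerol down (up, for the lower
        # leaflet) to the planted interdigitation depth past the midplane.
        # The chain direction carries the exact analytic tilt; the bead
        # spacing stretches to bridge attachment and tip, which is what a
        # geometric (not force-field) membrane can afford.  For nearly
        # flat tilts the vertical reach is capped (cos clamped), so very
        # low planted P2 shortens the realised penetration rather than
        # producing unbounded horizontal chains.
        n_tails = len(sp.tail_chains)
        cos_th, sin_th = np.cos(th), np.sin(th)
        z_attach = zr - 0.45
        dz = z_attach + depth  # vertical span attachment -> tip, > 0
        length = dz / np.maximum(cos_th, 0.45)
        for t, chain in enumerate(sp.tail_chains):
            ang = 2.0 * math.pi * t / n_tails
            ax = cx + TAIL_RING_RADIUS * math.cos(ang)
            ay = cy + TAIL_RING_RADIUS * math.sin(ang)
            phi = rng.uniform(0.0, 2.0 * math.pi, size=k)
            ux, uy = np.cos(phi) * sin_th * length, np.sin(phi) * sin_th * length
            n_b = len(chain)
            for kb, bname in enumerate(chain):
                frac = kb / (n_b - 1)
                z = sgn * (z_attach - frac * length * cos_th)
                bead_pos.append(
                    np.column_stack([ax + frac * ux, ay + frac * uy, z])
                )
                bead_names.append(bname)
        # interleave: all beads of lipid 0, then lipid 1, ...
        stacked = np.stack(bead_pos, axis=1)  # (k, n_beads, 3)
        pos_chunks.append(stacked.reshape(-1, 3))
        name_chunks.append(np.tile(np.array(bead_names, dtype=object), k))
        res_chunks.append(np.repeat(np.array([sname], dtype=object), k * sp.n_beads))
        lip_chunks.append(np.repeat(sel, sp.n_beads))

    positions = np.concatenate(pos_chunks)
    names = np.concatenate(name_chunks)
    resnames = np.concatenate(res_chunks)
    lipid_index = np.concatenate(lip_chunks)
    order = np.argsort(lipid_index, kind="stable")
    return positions[order], names[order], resnames[order], lipid_index[order]


def generate_membrane(
    config: GeneratorConfig,
) -> tuple[Trajectory, PlantedTruth]:
    """Generate the lipid bilayer trajectory and its planted ground truth.

    Lipids sit on a jittered lattice per leaflet.  Successive frames
    displace each lipid laterally by a Gaussian step with the leaflet's
    mobility sigma (a periodic random walk) — except lipids born inside
    one of their species' cluster regions, which stay confined to their
    anchor site (Gaussian jitter about it).  That mirrors the mechanism
    the membrane model emulates: void-trapped lipids are pinned while
    the rest of the leaflet diffuses freely, so planted clusters persist
    through the analysis window while the background ergodicises.  The
    internal geometry is rebuilt from the planted fields at the current
    position every frame.  Identical config + seed reproduces the output
    bit for bit.
    """
    config.validate()
    topo = config.topology()
    root = np.random.SeedSequence(config.seed)
    ss_upper, ss_lower, ss_dyn, ss_frames = root.spawn(4)
    plan_u = _plan_leaflet(config, "upper", np.random.default_rng(ss_upper))
    plan_l = _plan_leaflet(config, "lower", np.random.default_rng(ss_lower))
    rng_dyn = np.random.default_rng(ss_dyn)
    rng_frame = np.random.default_rng(ss_frames)

    n_u, n_l = len(plan_u.xy0), len(plan_l.xy0)
    lx, ly, lz = config.box
    z_shift = lz / 2.0

    frames: list[Frame] = []
    pos_hist = np.zeros((config.n_frames, n_u + n_l, 2))
    p2_hist = np.zeros((config.n_frames, n_u + n_l))
    pin_jitter = 0.15  # nm; rattle of a void-trapped (pinned) lipid
    xy_u, xy_l = plan_u.xy0.copy(), plan_l.xy0.copy()
    for f in range(config.n_frames):
        if f > 0:
            for xy, plan, sigma in (
                (xy_u, plan_u, config.mobility_sigma_upper),
                (xy_l, plan_l, config.mobility_sigma_lower),
            ):
                free = ~plan.cluster_member
                xy[free] += rng_dyn.normal(0.0, sigma, size=(int(free.sum()), 2))
                pinned = plan.cluster_member
                if pinned.any():
                    xy[pinned] = plan.xy0[pinned] + rng_dyn.normal(
                        0.0, min(sigma, pin_jitter), size=(int(pinned.sum()), 2)
                    )
                xy[:, 0] %= lx
                xy[:, 1] %= ly
        pos_u, names_u, res_u, lip_u = _build_lipid_beads(
            config, topo, plan_u, xy_u, "upper", rng_frame
        )
        pos_l, names_l, res_l, lip_l = _build_lipid_beads(
            config, topo, plan_l, xy_l, "lower", rng_frame
        )
        positions = np.concatenate([pos_u, pos_l])
        positions[:, 2] += z_shift
        resids = np.concatenate([lip_u + 1, lip_l + 1 + n_u])
        frames.append(
            Frame(
                positions=positions,
                box=np.array(config.box, dtype=float),
                names=np.concatenate([names_u, names_l]),
                resnames=np.concatenate([res_u, res_l]),
                resids=resids,
                time=f * config.dt_ps,
            )
        )
        pos_hist[f, :n_u] = xy_u
        pos_hist[f, n_u:] = xy_l
        p2_hist[f, :n_u] = _eval_field(config.order_field_upper, xy_u[:, 0], xy_u[:, 1])
        p2_hist[f, n_u:] = _eval_field(config.order_field_lower, xy_l[:, 0], xy_l[:, 1])

    truth = PlantedTruth(
        lipid_ids=np.arange(1, n_u + n_l + 1),
        species=np.concatenate([plan_u.species, plan_l.species]),
        leaflet=np.array(["upper"] * n_u + ["lower"] * n_l, dtype=object),
        positions=pos_hist,
        p2_target=p2_hist,
        cluster_member=np.concatenate([plan_u.cluster_member, plan_l.cluster_member]),
        void_member=np.concatenate([plan_u.void_member, plan_l.void_member]),
    )
    return Trajectory(frames, topo), truth


def membrane_z_extent(config: GeneratorConfig) -> tuple[float, float]:
    """Analytic z-range occupied by membrane beads (midplane at 0)."""
    topo = config.topology()
    top = 0.0
    for comp, sgn in ((config.composition_upper, 1), (config.composition_lower, -1)):
        for sname in comp:
            sp = topo[sname]
            reach = 0.5 * config.thickness + HEAD_SPACING * (len(sp.head_beads) + 1)
            top = max(top, reach)
    return (-top, top)


def generate_solvent(config: GeneratorConfig) -> Frame:
    """Water + antifreeze + neutralising ions in slabs flanking the membrane.

    Antifreeze bead count = round(antifreeze_fraction x water count); the
    default fraction 0.02 puts ~2% antifreeze among the water particles.
    Ion counts neutralise the lipid charges (Ca2+ for LPS pairs, Na+ for
    the rest).  Beads are placed uniformly at random within the slabs.
    """
    config.validate()
    if config.n_water < 1:
        raise GeneratorConfigError("positive water count required")
    lx, ly, lz = config.box
    lo, hi = membrane_z_extent(config)
    margin = 0.25
    slab_top = (lz / 2.0 + hi + margin, lz - 0.1)
    slab_bot = (0.1, lz / 2.0 + lo - margin)
    for z0, z1 in (slab_top, slab_bot):
        if z1 - z0 < BOND_LENGTH:
            raise GeneratorConfigError(
                "solvent slab thinner than one bead diameter; increase box z"
            )

    n_af = int(round(config.antifreeze_fraction * config.n_water))
    counts = largest_remainder_counts(config.composition_upper, config.lipids_per_leaflet)
    counts_l = largest_remainder_counts(config.composition_lower, config.lipids_per_leaflet)
    for s, c in counts_l.items():
        counts[s] = counts.get(s, 0) + c
    topo = config.topology()
    neg = sum(-topo[s].charge * c for s, c in counts.items() if topo[s].charge < 0)
    n_lps = sum(c for s, c in counts.items() if s == "LPS")
    n_ca = n_lps // 2
    n_na = max(0, neg - 2 * n_ca)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    groups = [("W", "W", config.n_water), ("WF", "WF", n_af)]
    if n_ca:
        groups.append(("ION", "CA", n_ca))
    if n_na:
        groups.append(("ION", "NA", n_na))
    pos_list, names, resnames = [], [], []
    for resname, bead, count in groups:
        if count == 0:
            continue
        pts = rng.uniform(size=(count, 3))
        pts[:, 0] *= lx
        pts[:, 1] *= ly
        # split between slabs proportionally to slab volume
        v_top = slab_top[1] - slab_top[0]
        v_bot = slab_bot[1] - slab_bot[0]
        take_top = rng.uniform(size=count) < v_top / (v_top + v_bot)
        z = np.where(
            take_top,
            slab_top[0] + pts[:, 2] * v_top,
            slab_bot[0] + pts[:, 2] * v_bot,
        )
        pos_list.append(np.column_stack([pts[:, 0], pts[:, 1], z]))
        names.append(np.repeat(np.array([bead], dtype=object), count))
        resnames.append(np.repeat(np.array([resname], dtype=object), count))
    positions = np.concatenate(pos_list)
    n = len(positions)
    return Frame(
        positions=positions,
        box=np.array(config.box, dtype=float),
        names=np.concatenate(names),
        resnames=np.concatenate(resnames),
        resids=np.arange(1, n + 1),
        time=0.0,
    )


def generate_system(config: GeneratorConfig) -> tuple[Trajectory, PlantedTruth]:
    """Full system: membrane trajectory with static solvent appended."""
    traj, truth = generate_membrane(config)
    solvent = generate_solvent(config)
    base = int(traj[0].resids.max())
    frames = []
    for fr in traj:
        frames.append(
            Frame(
                positions=np.concatenate([fr.positions, solvent.positions]),
                box=fr.box.copy(),
                names=np.concatenate([fr.names, solvent.names]),
                resnames=np.concatenate([fr.resnames, solvent.resnames]),
                resids=np.concatenate([fr.resids, solvent.resids + base]),
                time=fr.time,
            )
        )
    return Trajectory(frames, traj.topology), truth


# --------------------------------------------------------------------------
# synthetic beta-barrel proteins
# --------------------------------------------------------------------------


def generate_protein_barrel(
    n_strand_columns: int,
    diameter: float,
    length: float,
    bead_spacing: float = 0.47,
    twist_deg_per_row: float = 8.0,
    lumen_fill: bool = True,
) -> ProteinModel:
    """Bead cylinder standing in for a transmembrane beta barrel.

    ``n_strand_columns`` backbone bead columns are placed on a circle of
    the given diameter; rows run along z over the given length, each row
    rotated by a small twist (beta-barrel shear).  With ``lumen_fill``
    (default) a sparse bead lattice occupies the lumen at a few interior
    rows — the stand-in for the constriction loops real barrels fold into
    their pore, and what makes the alpha-shape hull of the xy projection
    well posed (a bare ring of cocircular points has no triangle with a
    small circumradius).
    """
    if n_strand_columns < 3:
        raise ValueError("a barrel needs at least 3 strand columns")
    if diameter <= 0 or length <= 0:
        raise ValueError("diameter and length must be positive")
    n_rows = max(2, int(round(length / bead_spacing)) + 1)
    zs = np.linspace(-length / 2.0, length / 2.0, n_rows)
    radius = diameter / 2.0
    twist = math.radians(twist_deg_per_row)
    pos = []
    names_list: list[np.ndarray] = []
    for i, z in enumerate(zs):
        ang = 2.0 * math.pi * np.arange(n_strand_columns) / n_strand_columns + i * twist
        pos.append(
            np.column_stack(
                [radius * np.cos(ang), radius * np.sin(ang), np.full(n_strand_columns, z)]
            )
        )
        names_list.append(np.repeat(np.array(["BB"], dtype=object), n_strand_columns))
    if lumen_fill and radius > 0.3:
        step = 0.4
        grid = np.arange(-radius, radius + step / 2, step)
        gx, gy = np.meshgrid(grid, grid, indexing="ij")
        inside = gx**2 + gy**2 <= (radius - 0.25) ** 2
        lumen_xy = np.column_stack([gx[inside], gy[inside]])
        if len(lumen_xy):
            for z in (-length / 4.0, 0.0, length / 4.0):
                pos.append(
                    np.column_stack([lumen_xy, np.full(len(lumen_xy), z)])
                )
                names_list.append(np.repeat(np.array(["LP"], dtype=object), len(lumen_xy)))
    positions = np.concatenate(pos)
    names = np.concatenate(names_list)
    return ProteinModel(
        positions=positions, names=names, principal_axis=np.array([0.0, 0.0, 1.0])
    )


def ompa_like_barrel() -> ProteinModel:
    """8-stranded barrel preset: ~5.6 nm long, ~2.2 nm across."""
    return generate_protein_barrel(8, 2.2, 5.6)


def ompf_monomer_like_barrel() -> ProteinModel:
    """16-stranded monomer preset: ~5.1 nm long, ~3.3 nm across."""
    return generate_protein_barrel(16, 3.3, 5.1)
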