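"""Density maps, thickness maps, partial density profiles, interdigitation."""

import math

import numpy as np
import pytest

from cgleaflet import (
    DensityProfile,
    Frame,
    GeneratorConfig,
    GridSpec,
    Trajectory,
    density_map,
    generate_membrane,
    interdigitation,
    mixed_phospholipid_config,
    partial_density_profile,
    thickness_map,
)
from cgleaflet.density import DEFAULT_PATCH_BOUNDS, GroupSelector
from conftest import tiny_frame_two_leaflets


class TestDensityMap:
    def test_one_lipid_per_quadrant(self, topo):
        frame = tiny_frame_two_leaflets(topo)  # 4 upper + 4 lower POPE refs
        traj = Trajectory([frame], topo)
        grid = GridSpec((0.0, 0.0), 2, 2, 2.0)
        m = density_map(traj, "upper", "POPE", topo, grid, window=1.0)
        assert np.allclose(m.values, 0.25)

    def test_unnormalized_sum_conserves_species_count(self, om_small, topo):
        _, traj, truth = om_small
        m = density_map(traj, "lower", "CDL", topo, window=1.0, normalized=False)
        n_cdl = int((truth.species == "CDL").sum())
        assert np.nansum(m.values) == pytest.approx(n_cdl, abs=1e-9)

    def test_planted_cluster_enrichment_ratio(self):
        centers = [(5.0, 5.0), (17.0, 12.0)]
        cfg = GeneratorConfig(
            lipids_per_leaflet=512,
            cluster_spec={"CDL": [(c, 2.5, 3.0) for c in centers]},
            mobility_sigma_lower=0.3,
            n_frames=50,
            seed=23,
        )
        traj, _ = generate_membrane(cfg)
        m = density_map(traj, "lower", "CDL", traj.topology, window=1.0)
        xc, yc = m.grid.cell_centers()
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        in_cluster = np.zeros(X.shape, bool)
        for cx, cy in centers:
            in_cluster |= (X - cx) ** 2 + (Y - cy) ** 2 <= 2.5**2
        ratio = m.values[in_cluster].mean() / m.values[~in_cluster].mean()
        assert 2.0 <= ratio <= 4.0

    def test_matches_brute_force_oracle(self, om_small, topo):
        _, traj, truth = om_small
        frame = traj[0]
        grid = GridSpec.for_box(frame.box, 1.0)
        m = density_map(
            Trajectory([frame], topo), "lower", "POPE", topo, grid, window=1.0
        )
        counts = np.zeros((grid.n_x, grid.n_y))
        lower = set(truth.leaflet_ids("lower").tolist())
        for i in range(frame.n_beads):
            if (
                frame.resnames[i] == "POPE"
                and frame.names[i] == topo["POPE"].ref_bead
                and int(frame.resids[i]) in lower
            ):
                ix, iy = grid.bin_index(frame.positions[i, :2])
                counts[ix[0], iy[0]] += 1
        oracle = counts / len(lower)
        assert np.abs(oracle - m.values).max() < 1e-12

    def test_empty_leaflet_species_rejected(self, om_small, topo):
        _, traj, _ = om_small
        with pytest.raises(ValueError, match="absent"):
            density_map(traj, "upper", "CDL", topo, window=1.0)


class TestThicknessMap:
    def test_flat_bilayer_thickness_everywhere(self, topo):
        cfg = GeneratorConfig(
            lipids_per_leaflet=200, thickness=4.0, n_frames=2, seed=3
        )
        traj, _ = generate_membrane(cfg)
        m = thickness_map(traj, traj.topology, window=1.0)
        assert np.allclose(m.values[m.occupied], 4.0, atol=1e-9)

    def test_void_annulus_thinner_than_background(self, om_medium, topo):
        cfg, traj, _ = om_medium
        m = thickness_map(traj, topo, window=0.5)
        xc, yc = m.grid.cell_centers()
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        near_void = np.zeros(X.shape, bool)
        for (cx, cy), r in cfg.void_regions:
            d2 = (X - cx) ** 2 + (Y - cy) ** 2
            near_void |= d2 <= r * r
        occ = m.occupied
        thin = m.values[near_void & occ].mean()
        background = m.values[~near_void & occ].mean()
        assert thin < background - 0.3

    def test_cell_with_single_leaflet_is_missing(self, topo):
        frame = tiny_frame_two_leaflets(topo)
        # move one lower lipid away so its old quadrant has upper only
        frame.positions[4, :2] = frame.positions[5, :2]
        traj = Trajectory([frame], topo)
        grid = GridSpec((0.0, 0.0), 2, 2, 2.0)
        m = thickness_map(traj, topo, grid, window=1.0)
        assert int(np.isnan(m.values).sum()) == 1
        assert np.allclose(m.values[m.occupied], 4.0)


class TestPartialDensityProfile:
    def test_uniform_beads_give_flat_profile(self, topo):
        # ideal-gas oracle: uniform z in the box implies equal expected
        # counts per interior bin (Poisson fluctuations only)
        rng = np.random.default_rng(31)
        n = 1_000_000  # patch covers 9/100 of the box; ~9e4 land inside
        box = np.array([10.0, 10.0, 20.0])
        water = rng.uniform(0, 1, size=(n, 3)) * box
        anchor = tiny_frame_two_leaflets(topo, box=tuple(box))
        frame = Frame(
            positions=np.vstack([anchor.positions, water]),
            box=box,
            names=np.append(anchor.names, ["W"] * n),
            resnames=np.append(anchor.resnames, ["W"] * n),
            resids=np.append(anchor.resids, np.arange(n) + 100),
        )
        traj = Trajectory([frame], topo)
        prof = partial_density_profile(
            traj,
            patch_bounds=(3.0, 6.0, 3.0, 6.0),
            groups={"water": GroupSelector(resnames=("W",))},
            topology=topo,
            bin_width=2.0,
            window=1.0,
        )
        d = prof.count_density["water"]
        z = prof.z_centers
        com = 5.0  # anchor lipids sit at z = 5 +/- 2
        interior = (z > 1.0 - com) & (z < box[2] - 1.0 - com)
        dens = d[interior]
        assert np.abs(dens / dens.mean() - 1.0).max() < 0.05

    def test_integral_returns_mean_bead_count(self, om_small, topo):
        from cgleaflet import generate_system

        cfg, _, _ = om_small
        traj, _ = generate_system(cfg)
        prof = partial_density_profile(traj, topology=topo, window=1.0)
        # conservation: sum(count density * bin volume) = mean count in patch
        total = prof.mean_count("water")
        counts = []
        x0, x1, y0, y1 = prof.patch_bounds
        for f in traj:
            xy = np.mod(f.positions[:, :2], f.box[:2])
            sel = (f.resnames == "W") | (f.resnames == "WF")
            inside = (
                (xy[:, 0] > x0) & (xy[:, 0] < x1) & (xy[:, 1] > y0) & (xy[:, 1] < y1)
            )
            counts.append(int((sel & inside).sum()))
        assert total == pytest.approx(np.mean(counts), abs=1e-9)

    def test_default_patch_bounds(self):
        assert DEFAULT_PATCH_BOUNDS == (6.0, 9.0, 16.0, 19.0)

    def test_strict_patch_boundaries_exclude_edge_beads(self, topo):
        frame = tiny_frame_two_leaflets(topo, box=(23.0, 23.0, 10.0))
        on_edge = frame.copy()
        on_edge.positions[0, :2] = [6.0, 17.0]  # exactly on x-boundary
        inside = frame.copy()
        inside.positions[0, :2] = [6.001, 17.0]
        g = {"refs": GroupSelector(role="ref", leaflet="any")}
        p_edge = partial_density_profile(
            Trajectory([on_edge], topo), groups=g, topology=topo, window=1.0
        )
        p_in = partial_density_profile(
            Trajectory([inside], topo), groups=g, topology=topo, window=1.0
        )
        assert p_edge.mean_count("refs") == pytest.approx(0.0, abs=1e-12)
        assert p_in.mean_count("refs") == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_patch_rejected(self, om_small, topo):
        _, traj, _ = om_small
        with pytest.raises(ValueError, match="patch"):
            partial_density_profile(
                traj, patch_bounds=(6.0, 6.0, 16.0, 19.0), topology=topo
            )
        with pytest.raises(ValueError, match="bin"):
            partial_density_profile(traj, topology=topo, bin_width=0.0)


class TestInterdigitation:
    def test_symmetric_membrane_zero_asymmetry(self):
        cfg = mixed_phospholipid_config(lipids_per_leaflet=400, n_frames=8, seed=19)
        traj, _ = generate_membrane(cfg)
        prof = partial_density_profile(traj, topology=traj.topology, window=0.5)
        rep = interdigitation(prof)
        assert abs(rep.asymmetry) <= 2 * prof.bin_width

    def test_planted_asymmetry_sign_and_size(self, om_small, topo):
        # planted: lower tails reach 1.0 nm up, upper tails 0.3 nm down
        _, traj, _ = om_small
        prof = partial_density_profile(traj, topology=topo, window=1.0)
        rep = interdigitation(prof)
        assert rep.asymmetry > 0
        assert rep.lower_into_upper > rep.upper_into_lower
        assert rep.lower_into_upper == pytest.approx(1.0, abs=0.3)

    def test_disjoint_tails_zero_overlap(self):
        z = np.linspace(-3, 3, 61)
        up = np.where(z > 1.0, 5.0, 0.0)
        lo = np.where(z < -1.0, 5.0, 0.0)
        prof = DensityProfile(
            z_centers=z,
            bin_width=0.1,
            patch_bounds=(0.0, 3.0, 0.0, 3.0),
            frames_used=1,
            count_density={"upper_tails": up, "lower_tails": lo},
            mass_density={"upper_tails": up * 72, "lower_tails": lo * 72},
        )
        assert interdigitation(prof).overlap == 0.0

    def test_missing_or_empty_groups_rejected(self):
        z = np.linspace(-3, 3, 61)
        prof = DensityProfile(
            z_centers=z,
            bin_width=0.1,
            patch_bounds=(0.0, 3.0, 0.0, 3.0),
            frames_used=1,
            count_density={"upper_tails": np.zeros_like(z)},
            mass_density={"upper_tails": np.zeros_like(z)},
        )
        with pytest.raises(ValueError, match="lower_tails"):
            interdigitation(prof)
        prof.count_density["lower_tails"] = np.zeros_like(z)
        with pytest.raises(ValueError, match="all-zero"):
            interdigitation(prof)
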