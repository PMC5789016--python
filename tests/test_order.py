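"""Per-lipid P2, gridded order maps, difference maps and centering."""

import numpy as np
import pytest

from cgleaflet import (
    Frame,
    GeneratorConfig,
    GridSpec,
    LipidSpecies,
    LipidTopology,
    ScalarMap2D,
    Trajectory,
    center_on_protein,
    difference_map,
    generate_membrane,
    lipid_order,
    order_map,
    species_order,
)
from cgleaflet.grid import GridMismatchError
from cgleaflet.presets import SinusoidalField


def one_tail_topology():
    """Custom species: a single 3-bead tail, so exactly two bonds."""
    topo = LipidTopology()
    topo.add(
        LipidSpecies(
            name="TST", ref_bead="PO4", tail_chains=(("C1", "C2", "C3"),)
        )
    )
    return topo


def tst_frame(c1, c2, c3, box=(10.0, 10.0, 10.0)):
    pos = np.array([[5.0, 5.0, 7.0], c1, c2, c3])
    return Frame(
        positions=pos,
        box=np.array(box),
        names=np.array(["PO4", "C1", "C2", "C3"], dtype=object),
        resnames=np.array(["TST"] * 4, dtype=object),
        resids=np.array([1, 1, 1, 1]),
    )


class TestLipidOrderClosedForms:
    def test_bonds_parallel_to_normal(self):
        topo = one_tail_topology()
        f = tst_frame([5, 5, 6.0], [5, 5, 5.5], [5, 5, 5.0])
        assert lipid_order(f, 1, topo) == pytest.approx(1.0)

    def test_bonds_in_plane(self):
        topo = one_tail_topology()
        f = tst_frame([5.5, 5, 6.0], [6.0, 5, 6.0], [6.0, 5.5, 6.0])
        assert lipid_order(f, 1, topo) == pytest.approx(-0.5)

    def test_one_parallel_one_perpendicular(self):
        topo = one_tail_topology()
        f = tst_frame([5, 5, 6.0], [5, 5, 5.5], [5.5, 5, 5.5])
        assert lipid_order(f, 1, topo) == pytest.approx(0.25)

    def test_zero_length_bond_rejected(self):
        topo = one_tail_topology()
        f = tst_frame([5, 5, 6.0], [5, 5, 6.0], [5, 5, 5.0])
        with pytest.raises(ValueError, match="zero-length"):
            lipid_order(f, 1, topo)

    def test_invariance_under_rigid_motion(self):
        topo = one_tail_topology()
        f = tst_frame([5.3, 5.1, 6.0], [5.6, 5.4, 5.6], [5.6, 5.9, 5.2])
        base = lipid_order(f, 1, topo)
        # rigid translation
        g = f.copy()
        g.positions += np.array([1.0, -0.5, 2.0])
        assert lipid_order(g, 1, topo) == pytest.approx(base, abs=1e-12)
        # rigid rotation about z
        ang = 0.7
        rot = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        h = f.copy()
        h.positions = (h.positions - 5.0) @ rot.T + 5.0
        assert lipid_order(h, 1, topo) == pytest.approx(base, abs=1e-12)

    def test_bounds_on_generated_membranes(self, om_small, topo):
        _, traj, _ = om_small
        for species in ("LPS", "POPE", "POPG", "CDL"):
            _, p2, _ = species_order(traj[0], topo, species)
            assert np.all(p2 >= -0.5 - 1e-12)
            assert np.all(p2 <= 1.0 + 1e-12)


class TestOrderMap:
    def test_uniform_planted_field_recovered_exactly(self):
        cfg = GeneratorConfig(
            lipids_per_leaflet=200,
            order_field_upper=0.4,
            order_field_lower=0.4,
            n_frames=4,
            seed=9,
        )
        traj, _ = generate_membrane(cfg)
        m = order_map(traj, "upper", traj.topology, window=1.0)
        assert np.allclose(m.values[m.occupied], 0.4, atol=1e-9)

    def test_sinusoidal_field_recovery(self):
        fld = SinusoidalField(0.4, 0.2, 23.0, 23.0)
        cfg = GeneratorConfig(
            lipids_per_leaflet=512,
            order_field_upper=fld,
            order_field_lower=0.4,
            mobility_sigma_upper=0.8,
            n_frames=10,
            seed=9,
        )
        traj, _ = generate_membrane(cfg)
        m = order_map(traj, "upper", traj.topology, window=1.0)
        xc, yc = m.grid.cell_centers()
        target = fld(*np.meshgrid(xc, yc, indexing="ij"))
        occ = m.occupied
        r = np.corrcoef(m.values[occ], target[occ])[0, 1]
        assert r > 0.9

    def test_map_error_shrinks_with_more_frames(self):
        fld = SinusoidalField(0.4, 0.2, 23.0, 23.0)

        def recovery(n_frames, seed):
            cfg = GeneratorConfig(
                lipids_per_leaflet=128,
                order_field_upper=fld,
                order_field_lower=0.4,
                mobility_sigma_upper=0.8,
                n_frames=n_frames,
                seed=seed,
            )
            traj, _ = generate_membrane(cfg)
            m = order_map(traj, "upper", traj.topology, window=1.0)
            xc, yc = m.grid.cell_centers()
            target = fld(*np.meshgrid(xc, yc, indexing="ij"))
            occ = m.occupied
            return np.corrcoef(m.values[occ], target[occ])[0, 1]

        assert recovery(50, seed=5) > recovery(5, seed=5)

    def test_single_lipid_single_frame(self):
        topo = one_tail_topology()
        f = tst_frame([5, 5, 6.0], [5, 5, 5.5], [5, 5, 5.0])
        # add a complete second lipid far below so leaflet assignment works
        lower = f.positions - np.array([0.0, 0.0, 5.0])
        g = Frame(
            positions=np.vstack([f.positions, lower]),
            box=f.box,
            names=np.append(f.names, f.names),
            resnames=np.append(f.resnames, f.resnames),
            resids=np.append(f.resids, [2] * 4),
        )
        traj = Trajectory([g], topo)
        m = order_map(traj, "upper", topo, window=1.0)
        assert m.counts.sum() == 1
        ix, iy = m.grid.bin_index([[5.0, 5.0]])
        assert m.values[ix[0], iy[0]] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, om_small, topo):
        _, traj, truth = om_small
        frame = traj[0]
        grid = GridSpec.for_box(frame.box, 1.0)
        sub = Trajectory([frame], topo)
        m = order_map(sub, "lower", topo, grid, window=1.0)
        # oracle: explicit per-lipid loop via the scalar lipid_order API
        sums = np.zeros((grid.n_x, grid.n_y))
        counts = np.zeros((grid.n_x, grid.n_y), dtype=int)
        for rid in truth.leaflet_ids("lower"):
            rid = int(rid)
            p2 = lipid_order(frame, rid, topo)
            sp = topo[str(frame.resnames[frame.resids == rid][0])]
            sel = (frame.resids == rid) & (frame.names == sp.ref_bead)
            ix, iy = grid.bin_index(frame.positions[sel, :2])
            sums[ix[0], iy[0]] += p2
            counts[ix[0], iy[0]] += 1
        assert np.array_equal(counts, m.counts)
        occ = counts > 0
        assert np.abs(sums[occ] / counts[occ] - m.values[occ]).max() < 1e-12

    def test_translation_equivariance(self, flat_bilayer):
        _, traj, _ = flat_bilayer
        grid = GridSpec.for_box(traj[0].box, 1.0)
        m0 = order_map(traj, "upper", traj.topology, grid, window=1.0)
        shift_cells = 3
        shifted = Trajectory(
            [
                Frame(
                    f.positions + np.array([shift_cells * grid.cell, 0.0, 0.0]),
                    f.box,
                    f.names,
                    f.resnames,
                    f.resids,
                    f.time,
                )
                for f in traj
            ],
            traj.topology,
        )
        m1 = order_map(shifted, "upper", traj.topology, grid, window=1.0)
        rolled = np.roll(m0.values, shift_cells, axis=0)
        both = ~np.isnan(rolled) & m1.occupied
        assert np.allclose(m1.values[both], rolled[both], atol=1e-12)


class TestDifferenceMap:
    def test_self_difference_is_zero(self, om_small, topo):
        _, traj, _ = om_small
        m = order_map(traj, "upper", topo, window=1.0)
        d = difference_map(m, m)
        assert np.allclose(d.values[d.occupied], 0.0)

    def test_anti_correlated_amplitudes_add(self):
        fld_u = SinusoidalField(0.5, 0.2, 23.0, 23.0)
        fld_l = SinusoidalField(0.5, -0.15, 23.0, 23.0)
        cfg = GeneratorConfig(
            lipids_per_leaflet=1024,
            order_field_upper=fld_u,
            order_field_lower=fld_l,
            mobility_sigma_upper=0.8,
            mobility_sigma_lower=0.8,
            n_frames=20,
            seed=17,
        )
        traj, _ = generate_membrane(cfg)
        mu = order_map(traj, "upper", traj.topology, window=1.0)
        ml = order_map(traj, "lower", traj.topology, grid=mu.grid, window=1.0)
        d = difference_map(mu, ml)
        amplitude = (np.nanmax(d.values) - np.nanmin(d.values)) / 2.0
        assert amplitude == pytest.approx(0.35, rel=0.2)

    def test_disjoint_occupancy_all_missing(self):
        grid = GridSpec((0.0, 0.0), 4, 4, 1.0)
        v1 = np.full((4, 4), np.nan)
        v2 = np.full((4, 4), np.nan)
        c1 = np.zeros((4, 4), int)
        c2 = np.zeros((4, 4), int)
        v1[:2], c1[:2] = 1.0, 1
        v2[2:], c2[2:] = 2.0, 1
        d = difference_map(
            ScalarMap2D(grid, v1, c1), ScalarMap2D(grid, v2, c2)
        )
        assert not d.occupied.any()

    def test_grid_mismatch_rejected(self):
        g1 = GridSpec((0.0, 0.0), 4, 4, 1.0)
        g2 = GridSpec((0.0, 0.0), 5, 5, 1.0)
        m1 = ScalarMap2D(g1, np.zeros((4, 4)), np.ones((4, 4), int))
        m2 = ScalarMap2D(g2, np.zeros((5, 5)), np.ones((5, 5), int))
        with pytest.raises(GridMismatchError):
            difference_map(m1, m2)


class TestCentering:
    def _with_protein(self, traj):
        from cgleaflet import ompa_like_barrel

        barrel = ompa_like_barrel()
        frames = []
        for f in traj:
            shift = np.array([3.0, 17.0, f.box[2] / 2])
            prot = barrel.positions + shift
            frames.append(
                Frame(
                    np.vstack([f.positions, prot]),
                    f.box,
                    np.append(f.names, barrel.names),
                    np.append(f.resnames, ["PROT"] * len(prot)),
                    np.append(f.resids, [f.resids.max() + 1] * len(prot)),
                    f.time,
                )
            )
        return Trajectory(frames, traj.topology)

    def test_protein_com_lands_on_box_center(self, flat_bilayer):
        _, traj, _ = flat_bilayer
        centered = center_on_protein(self._with_protein(traj), "PROT")
        for f in centered:
            com = f.positions[f.resnames == "PROT", :2].mean(axis=0)
            assert np.abs(com - f.box[:2] / 2).max() < 1e-6

    def test_lipids_stay_whole_after_wrapping(self, flat_bilayer, topo):
        _, traj, _ = flat_bilayer
        centered = center_on_protein(self._with_protein(traj), "PROT")
        f = centered[0]
        # max intra-residue xy spread must stay bounded (no split molecules)
        for rid in np.unique(f.resids)[:50]:
            xy = f.positions[f.resids == rid, :2]
            assert (xy.max(axis=0) - xy.min(axis=0)).max() < 5.0

    def test_empty_selection_rejected(self, flat_bilayer):
        _, traj, _ = flat_bilayer
        with pytest.raises(ValueError, match="PROT"):
            center_on_protein(traj, "PROT")
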