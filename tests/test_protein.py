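"""Concave hull, overlap detection and stochastic protein insertion."""

import numpy as np
import pytest
import shapely
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from cgleaflet import (
    ProteinModel,
    concave_hull_2d,
    find_overlaps,
    insert_protein,
    ompa_like_barrel,
)
from cgleaflet.protein import AlphaShapeError, InsertionError


def c_shape_points(n_theta=60, n_r=6, inner=1.0, outer=2.0, gap=np.pi / 2):
    """Dense filled C: annulus sector leaving a 90-degree mouth."""
    thetas = np.linspace(gap / 2, 2 * np.pi - gap / 2, n_theta)
    rs = np.linspace(inner, outer, n_r)
    pts = [(r * np.cos(t), r * np.sin(t)) for t in thetas for r in rs]
    return np.array(pts)


class TestConcaveHull:
    def test_square_convex_limit(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        poly = concave_hull_2d(square, alpha=100.0)
        assert poly.area == pytest.approx(1.0)

    def test_c_shape_smaller_than_convex_hull(self):
        pts = c_shape_points()
        poly = concave_hull_2d(pts, alpha=0.5)
        convex_area = ConvexHull(pts).volume  # 2D: volume is the area
        assert poly.area < 0.8 * convex_area

    def test_membership_matches_triangle_oracle(self):
        # oracle: a point is inside the alpha shape iff it lies in some
        # kept Delaunay triangle (barycentric test, recomputed here)
        pts = c_shape_points()
        alpha = 0.5
        poly = concave_hull_2d(pts, alpha)
        tri = Delaunay(pts)
        a, b, c = (pts[tri.simplices[:, k]] for k in range(3))
        la = np.linalg.norm(b - c, axis=1)
        lb = np.linalg.norm(a - c, axis=1)
        lc = np.linalg.norm(a - b, axis=1)
        area2 = np.abs(
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
            - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
        )
        keep = tri.simplices[(la * lb * lc / (2.0 * area2)) <= alpha]

        rng = np.random.default_rng(3)
        test_pts = rng.uniform(-2.2, 2.2, size=(10_000, 2))
        # skip points hugging the boundary; containment there is a tie
        off_boundary = (
            shapely.distance(poly.exterior, shapely.points(test_pts)) > 1e-6
        )
        in_poly = shapely.contains_xy(poly, test_pts[:, 0], test_pts[:, 1])

        # vectorised barycentric membership over all kept triangles
        in_tri = np.zeros(len(test_pts), dtype=bool)
        for s in keep:
            t = pts[s]
            m = np.array([t[1] - t[0], t[2] - t[0]]).T
            uv = np.linalg.solve(m, (test_pts - t[0]).T)
            in_tri |= (
                (uv[0] >= -1e-12) & (uv[1] >= -1e-12) & (uv.sum(axis=0) <= 1 + 1e-12)
            )
        assert not np.any((in_tri != in_poly) & off_boundary)

    def test_area_monotone_in_alpha(self):
        pts = c_shape_points()
        areas = [concave_hull_2d(pts, a).area for a in (0.4, 0.6, 1.0, 5.0)]
        assert all(a1 <= a2 + 1e-12 for a1, a2 in zip(areas, areas[1:]))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(AlphaShapeError):
            concave_hull_2d(pts, 1.0)

    def test_disconnected_regions_signalled(self):
        blob = np.random.default_rng(0).uniform(0, 1, size=(30, 2))
        two = np.vstack([blob, blob + 10.0])
        with pytest.raises(AlphaShapeError, match="disconnected|no triangle"):
            concave_hull_2d(two, 0.7)

    def test_too_small_alpha_signalled(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        with pytest.raises(AlphaShapeError, match="no triangle"):
            concave_hull_2d(square, 0.1)


@pytest.fixture(scope="module")
def placed(om_small):
    _, traj, _ = om_small
    frame = traj[0]
    barrel = ompa_like_barrel()
    center = np.array([frame.box[0] / 2, frame.box[1] / 2, frame.box[2] / 2])
    prot = barrel.translated(center)
    hull = concave_hull_2d(prot.positions[:, :2], 0.6)
    return frame, prot, hull


class TestFindOverlaps:
    def test_distant_lipid_not_flagged(self, placed, topo):
        frame, prot, hull = placed
        overlaps = find_overlaps(frame, topo, prot, hull, min_dist=0.1)
        refs = (frame.names == topo["POPE"].ref_bead) & (frame.resnames == "POPE")
        center = prot.positions[:, :2].mean(axis=0)
        far = np.linalg.norm(frame.positions[refs][:, :2] - center, axis=1) > 6.0
        far_ids = set(frame.resids[refs][far].tolist())
        assert not (far_ids & overlaps)

    def test_bead_inside_clash_distance_flagged(self, placed, topo):
        frame, prot, hull = placed
        f = frame.copy()
        # plant one lipid bead 0.05 nm from a protein bead, far from the hull
        victim = int(f.resids[f.resnames == "POPE"][0])
        sel = np.flatnonzero(f.resids == victim)
        probe = prot.positions[0] + np.array([0.03, 0.04, 0.0])
        f.positions[sel[0]] = probe
        overlaps = find_overlaps(f, topo, prot, hull, min_dist=0.1)
        assert victim in overlaps

    def test_matches_brute_force_oracle(self, placed, topo):
        frame, prot, hull = placed
        overlaps = find_overlaps(frame, topo, prot, hull, min_dist=0.35)
        # O(N*M) oracle with explicit minimum-image distances
        box = frame.box
        expected = set()
        lipid = np.zeros(frame.n_beads, dtype=bool)
        for s in topo.names():
            lipid |= frame.resnames == s
        pos = frame.positions[lipid]
        ids = frame.resids[lipid]
        for i in range(len(pos)):
            d = prot.positions - pos[i]
            d -= box * np.round(d / box)
            if (np.linalg.norm(d, axis=1) < 0.35).any():
                expected.add(int(ids[i]))
            elif shapely.contains_xy(hull, pos[i, 0] % box[0], pos[i, 1] % box[1]):
                expected.add(int(ids[i]))
        assert overlaps == expected

    def test_overlap_set_monotone_in_min_dist(self, placed, topo):
        frame, prot, hull = placed
        small = find_overlaps(frame, topo, prot, hull, min_dist=0.1)
        large = find_overlaps(frame, topo, prot, hull, min_dist=0.8)
        assert small <= large


class TestInsertProtein:
    def test_pocket_placement_removes_nothing(self, om_small, topo):
        _, traj, _ = om_small
        frame = traj[0]
        center = frame.box[:2] / 2
        refxy = frame.positions[:, :2]
        # dig a pocket: drop lipids whose any bead is within 5 nm of center
        d = np.linalg.norm(refxy - center, axis=1)
        bad = np.unique(frame.resids[(d < 5.0)])
        keep = frame.select(~np.isin(frame.resids, bad))
        result = insert_protein(
            keep, topo, ompa_like_barrel(), disk_radius=1.0, seed=4
        )
        assert result.removed == ()
        assert result.max_change_pp == pytest.approx(0.0)

    def test_seeded_reproducibility(self, om_small, topo):
        _, traj, _ = om_small
        r1 = insert_protein(traj[0], topo, ompa_like_barrel(), seed=11)
        r2 = insert_protein(traj[0], topo, ompa_like_barrel(), seed=11)
        assert r1.center == r2.center
        assert r1.removed == r2.removed
        r3 = insert_protein(traj[0], topo, ompa_like_barrel(), seed=12)
        assert r3.center != r1.center

    def test_no_surviving_clash_or_hull_violation(self, om_small, topo):
        _, traj, _ = om_small
        barrel = ompa_like_barrel()
        result = insert_protein(traj[0], topo, barrel, seed=5)
        f = result.frame
        prot = f.resnames == "PROT"
        lipid = np.zeros(f.n_beads, dtype=bool)
        for s in topo.names():
            lipid |= f.resnames == s
        tree = cKDTree(np.mod(f.positions[prot], f.box), boxsize=f.box)
        dists, _ = tree.query(np.mod(f.positions[lipid], f.box))
        assert dists.min() >= 0.1
        hull = concave_hull_2d(f.positions[prot][:, :2], 0.6)
        inside = shapely.contains_xy(
            hull, f.positions[lipid][:, 0], f.positions[lipid][:, 1]
        )
        assert not inside.any()

    def test_removed_set_matches_overlap_recomputation(self, om_small, topo):
        _, traj, _ = om_small
        barrel = ompa_like_barrel()
        result = insert_protein(traj[0], topo, barrel, seed=6)
        from cgleaflet import assign_leaflets

        mid = assign_leaflets(traj[0], topo).midplane_z
        placed = barrel.translated([result.center[0], result.center[1], mid])
        hull = concave_hull_2d(placed.positions[:, :2], 0.6)
        recomputed = find_overlaps(traj[0], topo, placed, hull, min_dist=0.1)
        assert set(result.removed) == recomputed

    def test_exhausted_attempts_reports_best(self, om_small, topo):
        _, traj, _ = om_small
        with pytest.raises(InsertionError) as err:
            insert_protein(
                traj[0], topo, ompa_like_barrel(), max_change=0.0, max_attempts=5, seed=1
            )
        assert err.value.best is not None
        assert err.value.best.max_change_pp >= 0.0

    def test_disk_outside_box_rejected(self, om_small, topo):
        _, traj, _ = om_small
        with pytest.raises(ValueError, match="disk"):
            insert_protein(
                traj[0], topo, ompa_like_barrel(), disk_center=(1.0, 1.0), seed=1
            )
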