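from math import gcd

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from airforge.centerline import (
    RadiusField,
    backtrack_path,
    build_network,
    detect_endpoints,
    interior_radius_field,
    solve_eikonal,
)
from airforge.synth import TreeSpec, make_tube_tree

# primitive step directions of the 5x5x5 neighborhood: a dense-stencil
# shortest-path graph keeps metrication error well under the comparison band
_ORACLE_DIRS = np.array(
    [
        (i, j, k)
        for i in range(-2, 3)
        for j in range(-2, 3)
        for k in range(-2, 3)
        if (i, j, k) != (0, 0, 0) and gcd(gcd(abs(i), abs(j)), abs(k)) == 1
    ]
)


def dijkstra_arrival_oracle(field: RadiusField, src_idx):
    """Independent arrival-time oracle: shortest path with cost ds / mean(r)."""
    mask = field.mask
    ids = -np.ones(mask.size, np.int64)
    interior = np.flatnonzero(mask.ravel())
    ids[interior] = np.arange(len(interior))
    idx3 = np.array(np.unravel_index(interior, mask.shape)).T
    r = field.radius.ravel()[interior]
    rows, cols, w = [], [], []
    for d in _ORACLE_DIRS:
        nb = idx3 + d
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        nbf = np.ravel_multi_index(nb[ok].T, mask.shape)
        srcv = interior[ok]
        valid = ids[nbf] >= 0
        i, j = ids[srcv[valid]], ids[nbf[valid]]
        length = np.linalg.norm(d) * field.pitch
        w.append(length * 0.5 * (1.0 / r[i] + 1.0 / r[j]))
        rows.append(i)
        cols.append(j)
    g = sparse.csr_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(interior),) * 2,
    )
    s = ids[np.ravel_multi_index(src_idx, mask.shape)]
    dist = dijkstra(g, indices=s, min_only=True)
    out = np.full(mask.shape, np.inf)
    out.ravel()[interior] = dist
    return out


class TestRadiusField:
    def test_cylinder_axis_radius(self, straight_tube):
        mesh, _ = straight_tube
        for pitch in (1.0, 0.5):
            f = interior_radius_field(mesh, pitch)
            ctr = f.world_to_index((0.0, 0.0, 20.0))
            assert abs(f.radius[ctr] - 4.0) <= pitch

    def test_sphere_center_radius(self):
        import trimesh

        ball = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        f = interior_radius_field(ball, 1.0)
        ctr = f.world_to_index((0.0, 0.0, 0.0))
        assert abs(f.radius[ctr] - 8.0) <= 1.0

    def test_too_coarse_pitch_rejected(self, straight_tube):
        mesh, _ = straight_tube
        with pytest.raises(ValueError, match="pitch"):
            interior_radius_field(mesh, 6.0)

    def test_radius_maxima_near_ground_truth_skeleton(self, closed_tree2):
        mesh, gt = closed_tree2
        f = interior_radius_field(mesh, 0.7)
        # every ground-truth centerline point must be in a high-radius voxel
        for p, r in zip(gt.points[::5], gt.radii[::5]):
            idx = f.world_to_index(p)
            assert f.radius[idx] > 0.5 * r


class TestEikonal:
    def test_uniform_speed_gives_geodesic_distance(self):
        mask = np.zeros((9, 9, 40), dtype=bool)
        mask[2:7, 2:7, 1:39] = True
        f = RadiusField(radius=np.where(mask, 1.0, 0.0), mask=mask, origin=np.zeros(3), pitch=1.0)
        arr = solve_eikonal(f, (4, 4, 1))
        assert arr.T[4, 4, 38] == pytest.approx(37.0, rel=0.02)

    def test_cylinder_far_end_arrival_close_to_length_over_radius(self, straight_tube):
        mesh, _ = straight_tube
        f = interior_radius_field(mesh, 0.5)
        arr = solve_eikonal(f, (0.0, 0.0, 2.0))
        t_far = arr.T[f.world_to_index((0.0, 0.0, 38.0))]
        assert t_far == pytest.approx(36.0 / 4.0, rel=0.1)

    def test_matches_dijkstra_oracle_on_random_field(self):
        from scipy.ndimage import gaussian_filter

        shape = (24, 24, 24)
        mask = np.ones(shape, dtype=bool)
        src = (2, 2, 2)
        idxg = np.indices(shape)
        euclid = np.sqrt(((idxg - np.array(src).reshape(3, 1, 1, 1)) ** 2).sum(0))
        rng = np.random.default_rng(1)
        noise = gaussian_filter(rng.normal(size=shape), 4)
        r = 1.0 + 0.3 * noise / np.abs(noise).max()
        f = RadiusField(radius=r, mask=mask, origin=np.zeros(3), pitch=1.0)
        arr = solve_eikonal(f, src)
        oracle = dijkstra_arrival_oracle(f, src)
        sel = euclid > 3  # both discretizations are arbitrary in the near field
        rel = np.abs(arr.T[sel] - oracle[sel]) / oracle[sel]
        assert rel.max() < 0.05

    def test_disconnected_region_stays_infinite(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[5:7, 5:7, 5:7] = True
        f = RadiusField(radius=np.where(mask, 1.0, 0.0), mask=mask, origin=np.zeros(3), pitch=1.0)
        arr = solve_eikonal(f, (1, 1, 1))
        assert np.isinf(arr.T[6, 6, 6])

    def test_source_outside_mask_rejected(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        f = RadiusField(radius=np.where(mask, 1.0, 0.0), mask=mask, origin=np.zeros(3), pitch=1.0)
        with pytest.raises(ValueError, match="source"):
            solve_eikonal(f, (0, 0, 0))


class TestBacktrack:
    def test_cylinder_path_hugs_axis(self, straight_tube):
        mesh, _ = straight_tube
        f = interior_radius_field(mesh, 1.0)
        arr = solve_eikonal(f, (0.0, 0.0, 2.0))
        pts, radii = backtrack_path(arr, (0.0, 0.0, 38.0))
        assert np.linalg.norm(pts[:, :2], axis=1).max() <= f.pitch
        assert np.all(radii > 0)

    def test_target_equals_source_single_point(self, straight_tube):
        mesh, _ = straight_tube
        f = interior_radius_field(mesh, 1.0)
        arr = solve_eikonal(f, (0.0, 0.0, 2.0))
        pts, _ = backtrack_path(arr, (0.0, 0.0, 2.0))
        assert len(np.unique(np.round(pts, 6), axis=0)) == 1

    def test_path_cost_consistent_with_arrival_time(self, straight_tube):
        mesh, _ = straight_tube
        f = interior_radius_field(mesh, 0.5)
        arr = solve_eikonal(f, (0.0, 0.0, 2.0))
        target = (0.0, 0.0, 38.0)
        pts, radii = backtrack_path(arr, target)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cost = float(np.sum(seg / (0.5 * (radii[:-1] + radii[1:]))))
        t_target = arr.T[f.world_to_index(target)]
        assert cost == pytest.approx(t_target, rel=0.1)

    def test_bend_path_stays_off_walls(self):
        mesh, _ = make_tube_tree(
            TreeSpec(generations=1, root_radius_mm=4.0, root_length_mm=20.0, half_angle_deg=45.0)
        )
        f = interior_radius_field(mesh, 0.7)
        arr = solve_eikonal(f, (0.0, 0.0, 2.0))
        # trace to one child tip
        tip = f.index_to_world(np.argwhere(f.mask)[np.argmax(np.argwhere(f.mask)[:, 0])])
        pts, radii = backtrack_path(arr, tip)
        # interior points keep at least half their inscribed radius of clearance
        assert np.all(radii[1:-1] >= 0.5 * f.pitch)

    def test_unreachable_target_rejected(self, straight_tube):
        mesh, _ = straight_tube
        f = interior_radius_field(mesh, 1.0)
        arr = solve_eikonal(f, (0.0, 0.0, 2.0))
        bad = arr.T.copy()
        arr.T[0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="unreachable"):
            backtrack_path(arr, (0, 0, 0))


class TestNetwork:
    def test_straight_tube_two_endpoints_one_branch(self, straight_tube):
        mesh, _ = straight_tube
        net = build_network(mesh, pitch=0.8)
        assert len(net.endpoints) == 2
        assert net.n_branches == 1

    def test_symmetric_tree_counts(self, closed_tree2):
        mesh, _ = closed_tree2
        net = build_network(mesh, pitch=0.7)
        assert len(net.endpoints) == 2**2 + 1
        assert net.n_branches == 2**3 - 1
        assert net.inlet in net.endpoints

    def test_inlet_has_largest_radius(self, closed_tree2):
        mesh, _ = closed_tree2
        net = build_network(mesh, pitch=0.7)
        eps = net.endpoints
        assert net.radii[net.inlet] == net.radii[eps].max()

    def test_branch_radii_decrease_with_generation(self):
        mesh, _ = make_tube_tree(TreeSpec(generations=2, decay=0.8))
        net = build_network(mesh, pitch=0.7)
        root_r = net.radii[net.inlet]
        terminal_rs = [net.radii[e] for e in net.endpoints if e != net.inlet]
        assert all(r < root_r for r in terminal_rs)

    def test_every_point_strictly_inside_mesh(self, closed_tree2):
        # analytic oracle: the tree solid is a union of capsules around the
        # generator segments, so signed distance is computable in closed form
        from airforge.synth import TreeSpec, _build_segments

        mesh, _ = closed_tree2
        net = build_network(mesh, pitch=0.7)
        segs = _build_segments(TreeSpec(generations=2))

        def inside(p):
            best = np.inf
            for s in segs:
                d = s.p1 - s.p0
                t = np.clip((p - s.p0) @ d / (d @ d), 0.0, 1.0)
                best = min(best, np.linalg.norm(p - s.p0 - t * d) - s.radius)
            return best < 0

        assert all(inside(p) for p in net.points)

    def test_endpoint_count_matches_generator_openings(self, open_tree3):
        _, gt = open_tree3
        closed, _ = make_tube_tree(TreeSpec(generations=3))
        net = build_network(closed, pitch=0.7)
        assert len(net.endpoints) == len(gt.endpoints) == 9

    def test_endpoints_stable_under_pitch_refinement(self, straight_tube):
        mesh, _ = straight_tube
        coarse = build_network(mesh, pitch=1.0)
        fine = build_network(mesh, pitch=0.5)
        ce = coarse.points[coarse.endpoints]
        fe = fine.points[fine.endpoints]
        for p in fe:
            assert np.linalg.norm(ce - p, axis=1).min() < 1.0 + 1e-9

    def test_detect_endpoints_tube(self, straight_tube):
        mesh, _ = straight_tube
        f = interior_radius_field(mesh, 1.0)
        eps = detect_endpoints(f)
        assert len(eps) == 2
        zs = sorted(f.index_to_world(e)[2] for e in eps)
        assert zs[0] < 10 and zs[1] > 30

    def test_json_round_trip(self, tmp_path, straight_tube):
        from airforge.network import CenterlineNetwork

        mesh, _ = straight_tube
        net = build_network(mesh, pitch=1.0)
        path = tmp_path / "net.json"
        net.save_json(path)
        back = CenterlineNetwork.load_json(path)
        assert np.allclose(back.points, net.points)
        assert back.inlet == net.inlet
        assert back.pitch == net.pitch
        assert sorted(back.graph.edges) == sorted(net.graph.edges)
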