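import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from airforge.capping import CapSpec, make_cap
from airforge.meshrepair import (
    TaubinParams,
    boundary_loops,
    edge_incidence,
    fill_holes,
    find_nonmanifold_edges,
    fix_winding,
    is_strictly_watertight,
    laplacian_smooth,
    load_stl,
    merge_close_vertices,
    quality_report,
    remove_nonmanifold,
    repair_to_watertight,
    save_stl,
    taubin_smooth,
)
from airforge.synth import TreeSpec, inject_defects, make_tube_tree


def tetra():
    return trimesh.Trimesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        faces=[[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]],
        process=False,
    )


class TestIncidence:
    def test_closed_tetrahedron_every_edge_twice(self):
        inc = edge_incidence(tetra())
        assert len(inc) == 6
        assert all(c == 2 for c in inc.values())

    def test_single_triangle_edges_once(self):
        tri = trimesh.Trimesh(vertices=np.eye(3), faces=[[0, 1, 2]], process=False)
        inc = edge_incidence(tri)
        assert len(inc) == 3
        assert all(c == 1 for c in inc.values())

    def test_fin_produces_one_triple_edge(self, icosphere_coarse):
        damaged, _ = inject_defects(icosphere_coarse, fins=1, seed=0)
        inc = edge_incidence(damaged)
        assert sorted(c for c in inc.values() if c != 2) == [1, 1, 3]


class TestNonmanifold:
    def test_watertight_tree_has_none(self, closed_tree2):
        mesh, _ = closed_tree2
        assert find_nonmanifold_edges(mesh) == set()

    def test_three_triangles_sharing_edge(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]],
            faces=[[0, 1, 2], [0, 1, 3], [0, 1, 4]],
            process=False,
        )
        assert find_nonmanifold_edges(mesh) == {(0, 1)}

    def test_open_strip_boundaries_are_not_nonmanifold(self):
        strip = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
            faces=[[0, 1, 2], [1, 3, 2]],
            process=False,
        )
        assert find_nonmanifold_edges(strip) == set()

    def test_removal_drops_all_incident_faces_and_orphans(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [5, 5, 5]],
            faces=[[0, 1, 2], [0, 1, 3], [0, 1, 4], [2, 3, 4]],
            process=False,
        )
        out, removed = remove_nonmanifold(mesh)
        assert removed == 3
        assert len(out.faces) == 1
        # orphaned vertices dropped; incidences now all <= 2
        assert len(out.vertices) == 3
        assert all(c <= 2 for c in edge_incidence(out).values())

    def test_clean_mesh_unchanged(self, icosphere_coarse):
        out, removed = remove_nonmanifold(icosphere_coarse)
        assert removed == 0
        assert len(out.faces) == len(icosphere_coarse.faces)

    def test_emptying_removal_raises(self):
        mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]],
            faces=[[0, 1, 2], [0, 1, 3], [0, 1, 4]],
            process=False,
        )
        with pytest.raises(ValueError, match="empty"):
            remove_nonmanifold(mesh)


class TestBoundaryLoops:
    def test_tetra_minus_face_one_triangle_cycle(self):
        t = tetra()
        open_t = trimesh.Trimesh(vertices=t.vertices, faces=t.faces[:3], process=False)
        loops = boundary_loops(open_t)
        assert len(loops) == 1
        assert len(loops[0]) == 3

    def test_open_tree_loop_count(self, open_tree3):
        mesh, _ = open_tree3
        assert len(boundary_loops(mesh)) == 2**3 + 1

    def test_watertight_mesh_has_no_loops(self, icosphere_coarse):
        assert boundary_loops(icosphere_coarse) == []


class TestFillHoles:
    def test_tetra_missing_face_restored(self):
        t = tetra()
        open_t = trimesh.Trimesh(vertices=t.vertices, faces=t.faces[:3], process=False)
        filled, counts = fill_holes(open_t)
        assert counts["3"] == 1
        assert len(filled.faces) == 4
        assert is_strictly_watertight(filled)
        assert abs(filled.volume) == pytest.approx(t.volume)

    def test_square_hole_becomes_two_triangles(self):
        box = trimesh.creation.box()
        # remove the two triangles of one quad face (+z)
        z = box.triangles_center[:, 2]
        keep = z < box.bounds[1, 2] - 1e-9
        holed = trimesh.Trimesh(vertices=box.vertices, faces=box.faces[keep], process=False)
        filled, counts = fill_holes(holed)
        assert counts["4"] == 1
        assert len(filled.faces) == len(holed.faces) + 2
        assert is_strictly_watertight(filled)

    def test_planar_hexagonal_hole_gets_loop_minus_two_triangles(self):
        prism = make_cap(CapSpec(np.zeros(3), np.array([0.0, 0.0, 1.0]), 2.0, 0.3))
        # remove the 4-triangle top fan -> hexagonal boundary loop
        top = prism.triangles_center[:, 2] > 0.149
        holed = trimesh.Trimesh(vertices=prism.vertices, faces=prism.faces[~top], process=False)
        assert len(boundary_loops(holed)) == 1
        filled, counts = fill_holes(holed)
        assert counts["5+"] == 1
        assert len(filled.faces) == len(holed.faces) + 4  # |h| - 2 = 4
        assert is_strictly_watertight(filled)

    def test_filled_mesh_has_consistent_winding(self):
        t = tetra()
        open_t = trimesh.Trimesh(vertices=t.vertices, faces=t.faces[:3], process=False)
        filled, _ = fill_holes(open_t)
        wound, _ = fix_winding(filled)
        assert wound.volume > 0


class TestRepair:
    def test_defect_round_trip_restores_volume(self, icosphere):
        damaged, _ = inject_defects(icosphere, holes=3, fins=1, flips=5, duplicates=2, seed=7)
        repaired, report = repair_to_watertight(damaged)
        assert report.watertight and report.manifold
        assert is_strictly_watertight(repaired)
        assert repaired.euler_number == 2
        assert abs(repaired.volume - icosphere.volume) / icosphere.volume < 0.01

    def test_clean_mesh_single_iteration_no_mods(self, icosphere_coarse):
        _, report = repair_to_watertight(icosphere_coarse)
        assert report.iterations == 1
        assert report.removed_nonmanifold_faces == 0
        assert sum(report.filled_holes.values()) == 0

    def test_idempotent(self, closed_tree2):
        mesh, _ = closed_tree2
        damaged, _ = inject_defects(mesh, holes=4, fins=2, flips=6, duplicates=3, seed=11)
        once, _ = repair_to_watertight(damaged)
        twice, report = repair_to_watertight(once)
        assert report.removed_nonmanifold_faces == 0
        assert sum(report.filled_holes.values()) == 0
        assert report.merged_vertices == 0
        assert len(twice.faces) == len(once.faces)

    def test_tree_euler_characteristic_two(self, closed_tree2):
        mesh, _ = closed_tree2
        damaged, _ = inject_defects(mesh, holes=5, fins=1, flips=3, duplicates=2, seed=13)
        repaired, _ = repair_to_watertight(damaged)
        assert repaired.euler_number == 2
        assert repaired.volume > 0
        inc = edge_incidence(repaired)
        assert all(c == 2 for c in inc.values())

    def test_invalid_max_iter(self, icosphere_coarse):
        with pytest.raises(ValueError):
            repair_to_watertight(icosphere_coarse, max_iter=0)


class TestMerge:
    def test_duplicates_merged_within_tolerance(self, icosphere_coarse):
        damaged, _ = inject_defects(icosphere_coarse, duplicates=3, seed=2)
        merged, n = merge_close_vertices(damaged)
        assert n == 3
        assert len(merged.vertices) == len(icosphere_coarse.vertices)

    def test_distant_vertices_untouched(self, icosphere_coarse):
        merged, n = merge_close_vertices(icosphere_coarse, eps=1e-5)
        assert n == 0


class TestTaubin:
    def test_zero_iterations_identity(self, icosphere_coarse):
        out = taubin_smooth(icosphere_coarse, TaubinParams(n_iter=0))
        assert np.array_equal(out.vertices, icosphere_coarse.vertices)

    def test_volume_preserved_vs_shrink_only(self, icosphere):
        t = taubin_smooth(icosphere, TaubinParams(0.60, 0.635, 20))
        l = laplacian_smooth(icosphere, 0.60, 20)
        dv_taubin = abs(t.volume - icosphere.volume) / icosphere.volume
        dv_lap = abs(l.volume - icosphere.volume) / icosphere.volume
        assert dv_taubin < 0.02
        assert dv_lap > 0.05
        assert dv_taubin < dv_lap

    def test_connectivity_and_watertightness_preserved(self, closed_tree2):
        mesh, _ = closed_tree2
        out = taubin_smooth(mesh, TaubinParams())
        assert np.array_equal(out.faces, mesh.faces)
        assert is_strictly_watertight(out)

    def test_stability_bound(self):
        p = TaubinParams(0.60, 0.635)
        assert 0.0 < p.stability_margin < 0.1
        assert p.stability_margin == pytest.approx(1 / 0.60 - 1 / 0.635)
        with pytest.raises(ValueError, match="stability"):
            TaubinParams(0.5, 0.9)  # margin 2 - 1.11 = 0.889

    def test_out_of_range_factors_rejected(self):
        with pytest.raises(ValueError):
            TaubinParams(lam=1.5)


class TestQuality:
    def test_equilateral_is_unity(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]],
            faces=[[0, 1, 2]],
            process=False,
        )
        assert quality_report(tri).shape_factor[0] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_is_zero(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [2, 0, 0]], faces=[[0, 1, 2]], process=False
        )
        q = quality_report(tri)
        assert q.shape_factor[0] == 0.0
        assert q.min_angle_deg[0] == 0.0

    def test_right_isoceles(self):
        tri = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]], process=False
        )
        q = quality_report(tri)
        assert q.shape_factor[0] == pytest.approx(np.sqrt(3) / 2)
        assert q.min_angle_deg[0] == pytest.approx(45.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=9))
    def test_shape_factor_matches_heron_oracle(self, coords):
        v = np.array(coords).reshape(3, 3)
        # Kahan's numerically stable Heron formula (sorted side lengths)
        a, b, c = sorted(
            (
                np.linalg.norm(v[1] - v[0]),
                np.linalg.norm(v[2] - v[1]),
                np.linalg.norm(v[0] - v[2]),
            ),
            reverse=True,
        )
        prod = max((a + (b + c)) * (c - (a - b)) * (c + (a - b)) * (a + (b - c)), 0.0)
        area = 0.25 * np.sqrt(prod)
        l2 = a * a + b * b + c * c
        expected = 4 * np.sqrt(3) * area / l2 if l2 > 0 else 0.0
        tri = trimesh.Trimesh(vertices=v, faces=[[0, 1, 2]], process=False)
        got = quality_report(tri).shape_factor[0]
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_min_angle_bounds(self, icosphere_coarse):
        q = quality_report(icosphere_coarse)
        assert np.all(q.shape_factor >= 0) and np.all(q.shape_factor <= 1 + 1e-12)
        assert np.all(q.min_angle_deg >= 0) and np.all(q.min_angle_deg <= 60 + 1e-9)


class TestWinding:
    def test_flipped_faces_restored(self, icosphere_coarse):
        damaged, _ = inject_defects(icosphere_coarse, flips=10, seed=9)
        fixed, n_flipped = fix_winding(damaged)
        assert n_flipped >= 10 or fixed.volume > 0
        assert fixed.volume == pytest.approx(icosphere_coarse.volume)

    def test_inverted_shell_reoriented(self, icosphere_coarse):
        inv = icosphere_coarse.copy()
        inv.invert()
        fixed, _ = fix_winding(inv)
        assert fixed.volume > 0


class TestStlIO:
    def test_round_trip_welds_soup(self, tmp_path, closed_tree2):
        mesh, _ = closed_tree2
        path = tmp_path / "tree.stl"
        save_stl(mesh, path)
        back = load_stl(path)
        assert is_strictly_watertight(back)
        assert back.volume == pytest.approx(mesh.volume, rel=1e-5)

    def test_ascii_format(self, tmp_path, icosphere_coarse):
        path = tmp_path / "ico.stl"
        save_stl(icosphere_coarse, path, ascii_format=True)
        assert path.read_bytes().startswith(b"solid")
        back = load_stl(path)
        assert back.volume == pytest.approx(icosphere_coarse.volume, rel=1e-4)
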