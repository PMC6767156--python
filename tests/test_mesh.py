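"""Mesh geometry: adjacency, areas, axial coordinate, plane selection."""

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from rvatlas.mesh import (
    MeshGeometry,
    axial_coordinate,
    build_adjacency,
    mean_correspondence_distance,
    plane_vertices,
    surface_area,
    face_areas,
)
from rvatlas.synthetic import generate_mesh


def make_mesh(vertices, faces, apex=None, annulus=None):
    vertices = np.asarray(vertices, float)
    n = len(vertices)
    return MeshGeometry(
        vertex_positions=vertices,
        faces=np.asarray(faces),
        landmark_apex=n - 1 if apex is None else apex,
        landmark_annulus=np.array([0]) if annulus is None else np.asarray(annulus),
        plane_point=np.zeros(3),
        plane_normal=np.array([0.0, 0.0, 1.0]),
    )


class TestAdjacency:
    def test_single_triangle_all_pairs_adjacent(self):
        m = make_mesh(np.eye(3), [[0, 1, 2]], apex=2, annulus=[0])
        A = build_adjacency(m).toarray()
        assert A[0, 1] and A[1, 2] and A[0, 2]
        assert not A.diagonal().any()

    def test_two_triangles_sharing_edge(self):
        verts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        m = make_mesh(verts, [[0, 1, 2], [1, 3, 2]], apex=3, annulus=[0])
        A = build_adjacency(m).toarray()
        assert not A[0, 3] and A[1, 2]

    def test_matches_brute_force_edge_scan(self, desk_mesh):
        A = build_adjacency(desk_mesh).toarray().astype(bool)
        B = np.zeros_like(A)
        for a, b, c in desk_mesh.faces:
            for i, j in ((a, b), (b, c), (c, a)):
                B[i, j] = B[j, i] = True
        assert (A == B).all()

    def test_degenerate_face_rejected(self):
        m = make_mesh(np.eye(3), [[0, 1, 1]], apex=2, annulus=[0])
        with pytest.raises(ValueError, match="degenerate"):
            build_adjacency(m)

    def test_generated_mesh_is_connected_manifold(self, desk_mesh):
        n_comp, _ = connected_components(desk_mesh.adjacency, directed=False)
        assert n_comp == 1
        # 2-manifold with boundary: each edge in at most 2 faces
        from collections import Counter

        edges = Counter()
        for a, b, c in desk_mesh.faces:
            for i, j in ((a, b), (b, c), (c, a)):
                edges[(min(i, j), max(i, j))] += 1
        assert max(edges.values()) <= 2


class TestSurfaceArea:
    def test_right_triangle_half_cm2(self):
        verts = [[0, 0, 0], [10, 0, 0], [0, 10, 0]]
        m = make_mesh(verts, [[0, 1, 2]], apex=2, annulus=[0])
        assert surface_area(m, [0, 1, 2]) == pytest.approx(0.5)

    def test_full_mesh_equals_sum_of_faces(self, desk_mesh):
        total = surface_area(desk_mesh)
        assert total == pytest.approx(face_areas(desk_mesh).sum() / 100.0)
        assert surface_area(desk_mesh, np.arange(desk_mesh.n_vertices)) == pytest.approx(total)

    def test_random_subset_matches_face_loop_oracle(self, desk_mesh):
        rng = np.random.default_rng(7)
        subset = rng.choice(desk_mesh.n_vertices, 300, replace=False)
        member = set(subset.tolist())
        oracle = sum(
            a for a, f in zip(face_areas(desk_mesh), desk_mesh.faces)
            if all(v in member for v in f)
        ) / 100.0
        assert surface_area(desk_mesh, subset) == pytest.approx(oracle, rel=1e-12)

    def test_empty_subset_warns_and_returns_zero(self, desk_mesh):
        with pytest.warns(UserWarning):
            assert surface_area(desk_mesh, np.array([], dtype=int)) == 0.0

    def test_additive_over_disjoint_face_complete_subsets(self, desk_mesh):
        # split the mesh by face parity into two vertex-complete subsets
        f = desk_mesh.faces
        half = desk_mesh.n_vertices // 2
        low = np.arange(half)
        high = np.arange(half, desk_mesh.n_vertices)
        a_low = surface_area(desk_mesh, low)
        a_high = surface_area(desk_mesh, high)
        # faces straddling the split belong to neither subset
        straddle = sum(
            ar for ar, face in zip(face_areas(desk_mesh), f)
            if (face < half).any() and (face >= half).any()
        ) / 100.0
        assert a_low + a_high + straddle == pytest.approx(surface_area(desk_mesh), rel=1e-9)

    def test_rigid_invariance(self, desk_mesh):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [0.4, -0.2, 1.1]).as_matrix()
        moved = MeshGeometry(
            vertex_positions=desk_mesh.vertex_positions @ R.T + np.array([3.0, -7.0, 2.0]),
            faces=desk_mesh.faces,
            landmark_apex=desk_mesh.landmark_apex,
            landmark_annulus=desk_mesh.landmark_annulus,
            plane_point=desk_mesh.plane_point,
            plane_normal=desk_mesh.plane_normal,
        )
        assert surface_area(moved) == pytest.approx(surface_area(desk_mesh), rel=1e-9)
        np.testing.assert_allclose(
            axial_coordinate(moved).fraction, axial_coordinate(desk_mesh).fraction,
            atol=1e-9,
        )


class TestAxialCoordinate:
    def test_apex_and_base_fractions(self, desk_mesh):
        ax = axial_coordinate(desk_mesh)
        assert ax.fraction[desk_mesh.landmark_apex] == pytest.approx(1.0)
        assert ax.distance_from_apex[desk_mesh.landmark_apex] == pytest.approx(0.0)
        # annulus ring lies in the base plane -> fraction 0
        np.testing.assert_allclose(ax.fraction[desk_mesh.landmark_annulus], 0.0, atol=1e-9)
        assert (ax.distance_from_apex >= 0).all()

    def test_mid_axis_vertex_fraction_half(self):
        # explicit fixture: base ring of 4 vertices at z=0, apex at z=-10,
        # probe vertex exactly halfway along the axis
        verts = [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0.5, 0, -5], [0, 0, -10]]
        faces = [[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4], [0, 1, 5], [1, 2, 5]]
        m = make_mesh(verts, faces, apex=5, annulus=[0, 1, 2, 3])
        ax = axial_coordinate(m)
        assert ax.fraction[4] == pytest.approx(0.5, abs=1e-9)
        assert ax.distance_from_apex[4] == pytest.approx(5.0, abs=1e-9)

    def test_zero_length_axis_raises(self):
        verts = [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 0, 0]]
        m = make_mesh(verts, [[0, 1, 2]], apex=3, annulus=[1, 2])
        with pytest.raises(ValueError, match="degenerate"):
            axial_coordinate(m)


class TestPlaneVertices:
    def test_inclusion_and_exclusion(self):
        verts = [[0, 0, 0], [1, 0, 0], [0, 1, 4.0], [0, 0, -10]]
        m = make_mesh(verts, [[0, 1, 2]], apex=3, annulus=[0])
        idx = plane_vertices(m, tolerance=2.0)
        assert 0 in idx and 1 in idx and 2 not in idx

    def test_matches_distance_oracle(self, desk_mesh):
        idx = plane_vertices(desk_mesh, 2.0)
        d = np.abs(desk_mesh.vertex_positions @ desk_mesh.plane_normal
                   - desk_mesh.plane_point @ desk_mesh.plane_normal)
        np.testing.assert_array_equal(idx, np.flatnonzero(d <= 2.0))

    def test_empty_result_warns(self, desk_mesh):
        far = MeshGeometry(
            vertex_positions=desk_mesh.vertex_positions,
            faces=desk_mesh.faces,
            landmark_apex=desk_mesh.landmark_apex,
            landmark_annulus=desk_mesh.landmark_annulus,
            plane_point=np.array([0.0, 500.0, 0.0]),
            plane_normal=np.array([0.0, 1.0, 0.0]),
        )
        with pytest.warns(UserWarning, match="no vertices"):
            plane_vertices(far, 0.5)


class TestCorrespondenceDistance:
    def test_identical_and_translated(self, desk_mesh):
        p = desk_mesh.vertex_positions
        res = mean_correspondence_distance(p, p)
        assert res["mean_mm"] == 0.0 and res["sd_mm"] == 0.0
        res = mean_correspondence_distance(p, p + np.array([1.0, 0, 0]))
        assert res["mean_mm"] == pytest.approx(1.0)
        assert res["sd_mm"] == pytest.approx(0.0, abs=1e-12)

    def test_random_perturbation_matches_loop(self, desk_mesh):
        rng = np.random.default_rng(3)
        p = desk_mesh.vertex_positions
        q = p + rng.normal(0, 0.5, p.shape)
        res = mean_correspondence_distance(p, q)
        d = [float(np.linalg.norm(a - b)) for a, b in zip(p, q)]
        assert res["mean_mm"] == pytest.approx(np.mean(d), rel=1e-12)
        assert res["sd_mm"] == pytest.approx(np.std(d, ddof=1), rel=1e-12)

    def test_count_mismatch_raises(self, desk_mesh):
        with pytest.raises(ValueError, match="mismatch"):
            mean_correspondence_distance(
                desk_mesh.vertex_positions, desk_mesh.vertex_positions[:-1]
            )


def test_apex_on_annulus_rejected():
    verts = np.eye(3)
    with pytest.raises(ValueError, match="apex"):
        MeshGeometry(
            vertex_positions=verts,
            faces=np.array([[0, 1, 2]]),
            landmark_apex=0,
            landmark_annulus=np.array([0, 1]),
            plane_point=np.zeros(3),
            plane_normal=np.array([0.0, 0, 1]),
        )


def test_generated_mesh_area_near_analytic():
    from rvatlas.synthetic import half_ellipsoid_area_cm2

    m = generate_mesh(500, axis_length_mm=70, radius_mm=25)
    analytic = half_ellipsoid_area_cm2(70, 25)
    assert surface_area(m) == pytest.approx(analytic, rel=0.10)
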