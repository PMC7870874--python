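import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actseg.geometry import (
    InvalidInputError,
    PointCloud,
    SurfaceMesh,
    Volume,
    build_knn_neighborhood,
    compute_normals,
    icosphere,
    one_sided_distance,
    point_distance,
    sample_trilinear,
    symmetric_distance,
    voxel_to_world,
    world_to_voxel,
)
from tests.conftest import cube_mesh


def brute_force_symmetric(a, b):
    d_ab = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return 0.5 * (d_ab.min(axis=1).mean() + d_ab.min(axis=0).mean())


class TestSymmetricDistance:
    def test_identity_is_zero(self, random_cloud):
        assert symmetric_distance(random_cloud, random_cloud) == 0.0

    def test_single_pair(self):
        a = PointCloud([[0.0, 0.0, 0.0]])
        b = PointCloud([[1.0, 0.0, 0.0]])
        assert symmetric_distance(a, b) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        a = rng.normal(size=(20, 3)) * 5
        b = rng.normal(size=(20, 3)) * 5
        assert symmetric_distance(PointCloud(a), PointCloud(b)) == pytest.approx(
            brute_force_symmetric(a, b), abs=1e-12
        )

    def test_symmetry_in_arguments(self, rng):
        a, b = rng.normal(size=(15, 3)), rng.normal(size=(9, 3))
        assert symmetric_distance(a, b) == symmetric_distance(b, a)

    def test_rigid_invariance(self, rng):
        from actseg.actions import euler_to_matrix

        a, b = rng.normal(size=(12, 3)), rng.normal(size=(17, 3))
        R = euler_to_matrix([0.3, -0.2, 0.9])
        t = np.array([5.0, -3.0, 2.0])
        before = symmetric_distance(a, b)
        after = symmetric_distance(a @ R.T + t, b @ R.T + t)
        assert after == pytest.approx(before, abs=1e-9)

    def test_empty_cloud_rejected(self):
        with pytest.raises(InvalidInputError):
            symmetric_distance(np.empty((0, 3)), np.zeros((1, 3)))


class TestPointDistance:
    def test_member_point(self, random_cloud):
        d, idx = point_distance(random_cloud.points[7], random_cloud)
        assert d == 0.0 and idx == 7

    def test_simple_pair(self):
        d, idx = point_distance([0, 0, 2], PointCloud([[0, 0, 0], [0, 0, 3]]))
        assert d == pytest.approx(1.0) and idx == 1

    def test_tie_breaks_lowest_index(self):
        d, idx = point_distance([0, 0, 0], PointCloud([[1, 0, 0], [-1, 0, 0]]))
        assert d == pytest.approx(1.0) and idx == 0

    def test_matches_linear_scan(self, rng):
        b = rng.normal(size=(50, 3))
        p = rng.normal(size=3)
        dists = np.linalg.norm(b - p, axis=1)
        d, idx = point_distance(p, PointCloud(b))
        assert idx == int(np.argmin(dists))
        assert d == pytest.approx(dists.min())


class TestKnnNeighborhood:
    def test_collinear_symmetrization(self):
        cloud = PointCloud([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        out = build_knn_neighborhood(cloud, k=1)
        # both end points pick the middle; middle picks one of them, then
        # symmetrization gives it both
        assert len(out.neighbors[1]) == 2

    def test_complete_graph(self, rng):
        cloud = PointCloud(rng.normal(size=(6, 3)))
        out = build_knn_neighborhood(cloud, k=5)
        for i, nb in enumerate(out.neighbors):
            assert len(nb) == 5 and i not in nb

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(30, 3))
        out = build_knn_neighborhood(PointCloud(pts), k=6)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        knn = [set(np.argsort(d[i], kind="stable")[:6]) for i in range(30)]
        expected = [set(s) for s in knn]
        for i in range(30):
            for j in knn[i]:
                expected[j].add(i)
        for i in range(30):
            assert set(out.neighbors[i]) == expected[i] - {i}

    def test_symmetry(self, rng):
        out = build_knn_neighborhood(PointCloud(rng.normal(size=(40, 3))), k=4)
        for i, nb in enumerate(out.neighbors):
            for j in nb:
                assert i in out.neighbors[j]

    def test_k_too_large_rejected(self, random_cloud):
        with pytest.raises(InvalidInputError):
            build_knn_neighborhood(random_cloud, k=len(random_cloud))


class TestNormals:
    def test_icosphere_radial(self):
        mesh = compute_normals(icosphere(4, radius=5.0))
        radial = mesh.points / np.linalg.norm(mesh.points, axis=1)[:, None]
        assert np.max(np.linalg.norm(mesh.normals - radial, axis=1)) < 1e-2

    def test_unit_norm(self, sphere_mesh):
        assert np.allclose(np.linalg.norm(sphere_mesh.normals, axis=1), 1.0, atol=1e-6)

    def test_cube_corner(self):
        mesh = compute_normals(cube_mesh())
        # corner at origin: three adjacent equal-area face normals average
        n = mesh.normals[0]
        expected = -np.ones(3) / np.sqrt(3)
        assert np.allclose(n, expected, atol=1e-9)

    def test_winding_flip_invariant(self, sphere_mesh):
        flipped = SurfaceMesh(
            sphere_mesh.points.copy(), None, sphere_mesh.faces[:, ::-1].copy()
        )
        out = compute_normals(flipped)
        assert np.allclose(out.normals, sphere_mesh.normals, atol=1e-12)

    def test_isolated_vertex_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5.0]])
        mesh = SurfaceMesh(pts, None, np.array([[0, 1, 2]]))
        with pytest.raises(InvalidInputError):
            compute_normals(mesh)


class TestCoordinateTransforms:
    def test_identity_affine(self, identity_volume, rng):
        pts = rng.normal(size=(5, 3))
        assert np.allclose(world_to_voxel(identity_volume, pts), pts)

    def test_diagonal_spacing(self):
        vol = Volume(np.zeros((4, 4, 4)), np.diag([2.0, 2.0, 2.0, 1.0]))
        assert np.allclose(world_to_voxel(vol, [[4.0, 4.0, 4.0]]), [[2, 2, 2]])

    def test_round_trip(self, rng):
        aff = np.eye(4)
        aff[:3, :3] = rng.normal(size=(3, 3)) + np.eye(3) * 3
        aff[:3, 3] = rng.normal(size=3) * 10
        vol = Volume(np.zeros((3, 3, 3)), aff)
        pts = rng.normal(size=(20, 3)) * 20
        back = voxel_to_world(vol, world_to_voxel(vol, pts))
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_singular_affine_rejected(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(InvalidInputError):
            Volume(np.zeros((2, 2, 2)), aff)

    def test_spacing_positive(self, phantom_case):
        _, vol, _, _ = phantom_case
        assert np.all(vol.spacing > 0)


class TestTrilinearSampling:
    def test_voxel_center(self, identity_volume):
        vals, oob = sample_trilinear(identity_volume, [[2.0, 3.0, 4.0]])
        assert vals[0] == identity_volume.data[2, 3, 4]
        assert not oob[0]

    def test_midpoint(self):
        data = np.zeros((2, 2, 2))
        data[1] = 1.0
        vol = Volume(data, np.eye(4))
        vals, _ = sample_trilinear(vol, [[0.5, 0.0, 0.0]])
        assert vals[0] == pytest.approx(0.5)

    def test_out_of_bounds_fill(self, identity_volume):
        vals, oob = sample_trilinear(identity_volume, [[100.0, 0.0, 0.0]])
        assert oob[0]
        assert vals[0] == identity_volume.data.min()

    def test_mm_based_resolution_independence(self):
        # analytic linear field sampled on two grids with different spacing
        def make(spacing):
            n = int(40 / spacing)
            idx = np.arange(n) * spacing
            data = idx[:, None, None] + np.zeros((n, n, n))
            aff = np.diag([spacing, spacing, spacing, 1.0])
            return Volume(data, aff)

        pts = np.random.default_rng(3).uniform(5, 30, size=(50, 3))
        v1, _ = sample_trilinear(make(1.0), pts)
        v2, _ = sample_trilinear(make(0.5), pts)
        assert np.max(np.abs(v1 - v2)) < 1e-9  # linear field: interp exact


@settings(max_examples=25, deadline=None)
@given(
    st.integers(min_value=2, max_value=12),
    st.integers(min_value=2, max_value=12),
    st.integers(min_value=0, max_value=10_000),
)
def test_symmetric_distance_properties(n_a, n_b, seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=(n_a, 3)), rng.normal(size=(n_b, 3))
    d = symmetric_distance(a, b)
    assert d >= 0
    assert d == symmetric_distance(b, a)
    assert d == pytest.approx(brute_force_symmetric(a, b), abs=1e-12)


def test_one_sided_vs_symmetric(rng):
    a, b = rng.normal(size=(10, 3)), rng.normal(size=(14, 3))
    assert symmetric_distance(a, b) == pytest.approx(
        0.5 * (one_sided_distance(a, b) + one_sided_distance(b, a))
    )
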