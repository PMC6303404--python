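import numpy as np
import pytest
import trimesh
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

from perivasc.proximity import (
    DistanceProfile,
    EmptyMeshError,
    MeshDistanceQuery,
    distance_profile,
    enrichment,
    min_distance_to_mesh,
    perivascular_fraction,
    simulate_null,
)
from perivasc.volume_io import TriMesh


class TestPointMeshDistance:
    def test_point_on_vertex_is_zero(self, torus_mesh_500):
        v = torus_mesh_500.vertices[7]
        assert min_distance_to_mesh(v, torus_mesh_500) == pytest.approx(0.0, abs=1e-12)

    def test_height_above_square_face(self):
        # two triangles tile the unit square in z=0; a point above the
        # interior is exactly its height away
        verts = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        mesh = TriMesh(verts, [[0, 1, 2], [0, 2, 3]])
        assert min_distance_to_mesh([0.3, 0.6, 0.25], mesh) == pytest.approx(0.25, abs=1e-12)
        # beyond the edge, distance is to the boundary
        assert min_distance_to_mesh([2.0, 0.5, 0.0], mesh) == pytest.approx(1.0, abs=1e-12)

    def test_accelerated_equals_exhaustive(self, torus_mesh_500):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-16, 16, (100, 3))
        q = MeshDistanceQuery(torus_mesh_500)
        acc = q.distances(pts)
        exh = q.distances(pts, exhaustive=True)
        np.testing.assert_allclose(acc, exh, rtol=1e-9)

    def test_agrees_with_independent_brute_force(self, torus_mesh_500):
        # trimesh's naive closest-point scan is an independent implementation
        rng = np.random.default_rng(3)
        pts = rng.uniform(-16, 16, (50, 3))
        q = MeshDistanceQuery(torus_mesh_500)
        _, d_ref, _ = trimesh.proximity.closest_point_naive(torus_mesh_500.to_trimesh(), pts)
        np.testing.assert_allclose(q.distances(pts), d_ref, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, torus_mesh_500, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-16, 16, (25, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-30, 30, 3)
        d0 = MeshDistanceQuery(torus_mesh_500).distances(pts)
        moved = torus_mesh_500.transformed(rotation=rot, translation=shift)
        d1 = MeshDistanceQuery(moved).distances(pts @ rot.T + shift)
        np.testing.assert_allclose(d0, d1, rtol=1e-9, atol=1e-9)

    def test_within_matches_distances(self, cylinder_mesh):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, (2000, 3))
        q = MeshDistanceQuery(cylinder_mesh)
        thr = np.array([3.0, 10.0, 25.0])
        expected = q.distances(pts)[:, None] <= thr[None, :]
        np.testing.assert_array_equal(q.within(pts, thr), expected)

    def test_empty_mesh_rejected(self):
        empty = TriMesh(np.empty((0, 3)), np.empty((0, 3), int))
        with pytest.raises(EmptyMeshError):
            min_distance_to_mesh([0, 0, 0], empty)


_coord = st.floats(-10.0, 10.0, allow_nan=False, width=64)


class TestPointTriangleProperties:
    @settings(max_examples=100, deadline=None)
    @given(
        p=arrays(np.float64, (3,), elements=_coord),
        tri=arrays(np.float64, (3, 3), elements=_coord),
        shift=arrays(np.float64, (3,), elements=_coord),
    )
    def test_permutation_and_translation_invariance(self, p, tri, shift):
        """The point-triangle distance does not depend on vertex order and
        commutes with rigid translation; it is bounded above by the nearest
        vertex and below by zero. Zero-area faces are outside the contract
        (TriMesh drops them at construction)."""
        from perivasc.proximity import _point_triangle_distance

        area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        assume(area > 1e-6)
        d = _point_triangle_distance(p[None], tri[None])[0]
        assert d >= 0
        assert d <= np.linalg.norm(tri - p, axis=1).min() + 1e-9
        for perm in ([1, 2, 0], [2, 1, 0]):
            d_perm = _point_triangle_distance(p[None], tri[perm][None])[0]
            assert d_perm == pytest.approx(d, abs=1e-9)
        d_shift = _point_triangle_distance((p + shift)[None], (tri + shift)[None])[0]
        assert d_shift == pytest.approx(d, abs=1e-7)

    @settings(max_examples=50, deadline=None)
    @given(
        tri=arrays(np.float64, (3, 3), elements=_coord),
        bary=arrays(np.float64, (3,), elements=st.floats(0.01, 1.0, width=64)),
    )
    def test_points_on_triangle_have_zero_distance(self, tri, bary):
        from perivasc.proximity import _point_triangle_distance

        area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        assume(area > 1e-6)
        bary = bary / bary.sum()
        p = bary @ tri
        scale = max(np.linalg.norm(np.ptp(tri, axis=0)), 1.0)
        assert _point_triangle_distance(p[None], tri[None])[0] <= 1e-7 * scale


class TestMeshContains:
    def test_winding_number_matches_analytic_cylinder(
        self, cylinder_mesh, cylinder_interior
    ):
        from perivasc.proximity import mesh_contains

        rng = np.random.default_rng(31)
        pts = rng.uniform(0, 100, (400, 3))
        # skip points within half a voxel-ish band of the faceted surface,
        # where the polygonal mesh and the ideal cylinder legitimately differ
        radial = np.abs(np.linalg.norm(pts[:, :2] - 50, axis=1) - 5.0)
        clear = radial > 0.05
        inside = mesh_contains(cylinder_mesh, pts)
        np.testing.assert_array_equal(inside[clear], cylinder_interior(pts)[clear])


class TestDistanceProfile:
    def test_touching_object_in_first_bin(self, cylinder_mesh):
        profile = distance_profile([[55.0, 50.0, 50.0]], [cylinder_mesh])
        assert profile.distances[0] == pytest.approx(0.0, abs=0.02)
        assert profile.counts[0] == 1

    def test_histogram_conserves_counts(self, cylinder_mesh):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (200, 3))
        profile = distance_profile(pts, [cylinder_mesh])
        assert profile.counts.sum() == 200
        assert profile.count_within(np.inf) == 200
        cum = profile.count_within(np.arange(0.0, 80.0))
        assert np.all(np.diff(cum) >= 0)

    def test_min_over_multiple_meshes_matches_brute_force(self):
        rng = np.random.default_rng(7)
        meshes = []
        for k in range(3):
            ball = trimesh.creation.icosphere(subdivisions=1, radius=2.0)
            ball.apply_translation(rng.uniform(10, 90, 3))
            meshes.append(TriMesh.from_trimesh(ball))
        pts = rng.uniform(0, 100, (50, 3))
        profile = distance_profile(pts, meshes)
        per_mesh = np.stack([MeshDistanceQuery(m).distances(pts, exhaustive=True) for m in meshes])
        np.testing.assert_allclose(profile.distances, per_mesh.min(axis=0), rtol=1e-9)

    def test_empty_profile_is_valid(self, cylinder_mesh):
        profile = distance_profile(np.empty((0, 3)), [cylinder_mesh])
        assert profile.n == 0
        assert profile.fraction_within(10.0) == 0.0


class TestSimulateNull:
    def test_r_must_be_positive(self, cylinder_mesh, box_100):
        with pytest.raises(ValueError):
            simulate_null(10, box_100, [cylinder_mesh], R=0, seed=1)

    def test_small_r_warns(self, cylinder_mesh, box_100, cylinder_interior):
        with pytest.warns(UserWarning, match="unstable"):
            simulate_null(5, box_100, [cylinder_mesh], R=50, seed=1,
                          interior_fn=cylinder_interior)

    def test_saturation_at_domain_diameter(self, box_100):
        # the box's own boundary surface: every interior point is within the
        # domain diameter, so the count saturates at n
        shell = trimesh.creation.box(extents=(100, 100, 100))
        shell.apply_translation([50, 50, 50])
        mesh = TriMesh.from_trimesh(shell)
        env = simulate_null(20, box_100, [mesh], R=100, seed=3,
                            thresholds=[100.0 * np.sqrt(3)], exclude_interior=False)
        assert np.all(env.count_samples == 20)
        assert env.expectation[0] == 20

    def test_envelope_matches_binomial_variance(self, cylinder_mesh, box_100, cylinder_interior):
        # counts within d are Binomial(n, p): variance within 10% at R=2000
        env = simulate_null(100, box_100, [cylinder_mesh], R=2000, seed=9,
                            thresholds=[10.0], interior_fn=cylinder_interior)
        L, V = 100.0, 1e6
        p = np.pi * (15**2 - 5**2) * L / (V - np.pi * 25 * L)
        assert env.expectation[0] == pytest.approx(100 * p, rel=0.05)
        assert env.variance[0] == pytest.approx(100 * p * (1 - p), rel=0.10)

    def test_determinism(self, cylinder_mesh, box_100, cylinder_interior):
        kw = dict(thresholds=[5.0, 10.0], interior_fn=cylinder_interior)
        a = simulate_null(30, box_100, [cylinder_mesh], R=150, seed=4, **kw)
        b = simulate_null(30, box_100, [cylinder_mesh], R=150, seed=4, **kw)
        np.testing.assert_array_equal(a.count_samples, b.count_samples)


class TestEnrichment:
    def test_null_consistent_observation_has_p_half(self, cylinder_mesh, box_100, cylinder_interior):
        env = simulate_null(259, box_100, [cylinder_mesh], R=2000, seed=21,
                            thresholds=[10.0], interior_fn=cylinder_interior)
        target = int(round(env.expectation[0]))
        # profile with exactly the null-mean count inside the threshold
        d = np.concatenate([np.full(target, 1.0), np.full(259 - target, 50.0)])
        report = enrichment(DistanceProfile(d), env)
        assert report.p_empirical[0] == pytest.approx(0.5, abs=0.1)

    def test_p_values_in_unit_interval(self, cylinder_mesh, box_100, cylinder_interior):
        env = simulate_null(50, box_100, [cylinder_mesh], R=200, seed=2,
                            thresholds=[5.0, 10.0], interior_fn=cylinder_interior)
        d = np.full(50, 0.5)
        report = enrichment(DistanceProfile(d), env)
        assert np.all(report.p_empirical > 0)
        assert np.all(report.p_empirical <= 1)
        assert report.p_empirical[0] == pytest.approx(1.0 / 201.0)


class TestPerivascularFraction:
    def test_all_touching_gives_100(self):
        assert perivascular_fraction(DistanceProfile(np.zeros(10)), 10.0) == 100.0

    def test_two_thirds_within(self):
        profile = DistanceProfile(np.array([1.0, 2.0, 20.0]))
        assert perivascular_fraction(profile, 10.0) == pytest.approx(66.7, abs=0.05)

    def test_uniform_placement_matches_null_expectation(
        self, cylinder_mesh, box_100, cylinder_interior
    ):
        from perivasc.proximity import sample_points

        rng = np.random.default_rng(17)
        pts = sample_points(500, box_100, rng, interior_fn=cylinder_interior)
        profile = distance_profile(pts, [cylinder_mesh])
        env = simulate_null(500, box_100, [cylinder_mesh], R=500, seed=18,
                            thresholds=[10.0], interior_fn=cylinder_interior)
        se = np.sqrt(env.variance[0])
        observed = profile.count_within(10.0)
        assert abs(observed - env.expectation[0]) <= 3 * se

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            perivascular_fraction(DistanceProfile(np.zeros(3)), 0.0)
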