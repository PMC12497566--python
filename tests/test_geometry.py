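"""Core geometry: sphere fitting, nearest-point queries, rotations,
projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from hipmma.geometry import (
    DegenerateGeometryError,
    RigidTransform,
    Sphere,
    closest_point_on_triangles,
    fit_sphere,
    nearest_point_on_segment,
    project_vector_onto_plane,
    rotate_about_axis,
    rotation_about_axis_matrix,
)

finite = st.floats(-50.0, 50.0, allow_nan=False)
vec3 = st.tuples(finite, finite, finite).map(np.array)


def sphere_points(center, radius, n, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v


def geometric_sphere_fit(points):
    """Independent oracle: nonlinear least squares on the orthogonal
    (geometric) distance, seeded at the centroid."""
    P = np.asarray(points, float)

    def residuals(x):
        return np.linalg.norm(P - x[:3], axis=1) - x[3]

    x0 = np.r_[P.mean(axis=0), P.std()]
    return least_squares(residuals, x0).x


class TestFitSphere:
    def test_circumsphere_of_four_points(self):
        s = fit_sphere([(0, 0, 0), (2, 0, 0), (0, 2, 0), (0, 0, 2)])
        assert np.allclose(s.center, (1, 1, 1), atol=1e-12)
        assert s.radius == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_exact_recovery_from_clean_samples(self):
        rng = np.random.default_rng(0)
        pts = sphere_points((1, 2, 3), 5.0, 200, rng)
        s = fit_sphere(pts)
        assert np.allclose(s.center, (1, 2, 3), atol=1e-9)
        assert s.radius == pytest.approx(5.0, abs=1e-9)

    def test_noisy_fit_matches_geometric_oracle(self):
        rng = np.random.default_rng(1)
        pts = sphere_points((1, 2, 3), 5.0, 200, rng) + rng.normal(0, 0.05, (200, 3))
        s = fit_sphere(pts)
        cx, cy, cz, r = geometric_sphere_fit(pts)
        assert np.linalg.norm(s.center - (1, 2, 3)) < 0.02
        assert np.linalg.norm(s.center - (cx, cy, cz)) < 5e-3
        assert abs(s.radius - r) < 5e-3

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(2)
        pts = sphere_points((0, 0, 0), 3.0, 50, rng)
        axis = rng.normal(size=3)
        R = rotation_about_axis_matrix(axis / np.linalg.norm(axis), 37.0)
        T = RigidTransform(R, np.array([4.0, -2.0, 7.0]))
        fit_then_move = T.apply(fit_sphere(pts).center)
        move_then_fit = fit_sphere(T.apply(pts)).center
        assert np.allclose(fit_then_move, move_then_fit, atol=1e-9)

    @pytest.mark.parametrize(
        "points",
        [
            [(0, 0, 0), (1, 0, 0), (0, 1, 0)],  # too few
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (0.3, 0.7, 0)],  # coplanar
        ],
    )
    def test_degenerate_configurations_raise(self, points):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(points)

    def test_sphere_requires_positive_radius(self):
        with pytest.raises(ValueError):
            Sphere(center=(0, 0, 0), radius=-1.0)


class TestNearestPoint:
    @pytest.mark.parametrize(
        "a,b,q,clamp,point,dist",
        [
            ((1, -1, 0), (1, 1, 0), (0, 0, 0), True, (1, 0, 0), 1.0),
            ((1, 1, 0), (1, 2, 0), (0, 0, 0), True, (1, 1, 0), np.sqrt(2)),
            ((0, 5, 0), (3, -4, 0), (0, 0, 0), False, (1.5, 0.5, 0), 5 / np.sqrt(10)),
        ],
    )
    def test_examples(self, a, b, q, clamp, point, dist):
        p, d = nearest_point_on_segment(a, b, q, clamp=clamp)
        assert np.allclose(p, point, atol=1e-12)
        assert d == pytest.approx(dist, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(vec3, vec3, vec3)
    def test_unclamped_distance_matches_cross_product_form(self, a, b, q):
        d = b - a
        if np.linalg.norm(d) < 1e-3:
            return
        _, dist = nearest_point_on_segment(a, b, q, clamp=False)
        expected = np.linalg.norm(np.cross(q - a, d)) / np.linalg.norm(d)
        assert dist == pytest.approx(expected, abs=1e-9)

    def test_coincident_endpoints_raise(self):
        with pytest.raises(DegenerateGeometryError):
            nearest_point_on_segment((1, 1, 1), (1, 1, 1), (0, 0, 0))


class TestRotation:
    def test_quarter_turn_about_z(self):
        p = rotate_about_axis((1, 0, 0), (0, 0, 0), (0, 0, 1), 90.0)
        assert np.allclose(p, (0, 1, 0), atol=1e-12)

    def test_zero_angle_is_identity(self):
        p = np.array([3.1, -2.2, 0.7])
        assert np.array_equal(rotate_about_axis(p, (1, 2, 3), (0, 1, 0), 0.0), p)

    def test_half_turn_about_offset_axis(self):
        p = rotate_about_axis((2, 0, 0), (1, 0, 0), (0, 0, 1), 180.0)
        assert np.allclose(p, (0, 0, 0), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(vec3, vec3, st.floats(-360, 360))
    def test_corotation_preserves_pairwise_distance(self, p, q, angle):
        axis_point = np.array([1.0, -2.0, 0.5])
        axis = np.array([0.3, 0.5, 0.81])
        p2 = rotate_about_axis(p, axis_point, axis, angle)
        q2 = rotate_about_axis(q, axis_point, axis, angle)
        assert np.linalg.norm(p2 - q2) == pytest.approx(
            np.linalg.norm(p - q), abs=1e-9
        )


class TestProjection:
    @pytest.mark.parametrize(
        "v,n,out,length",
        [
            ((3, 4, 0), (1, 0, 0), (0, 4, 0), 4.0),
            ((0, 0, 5), (0, 0, 1), (0, 0, 0), 0.0),
            ((1, 1, 1), (0, 0, 1), (1, 1, 0), np.sqrt(2)),
        ],
    )
    def test_examples(self, v, n, out, length):
        w, l = project_vector_onto_plane(v, n)
        assert np.allclose(w, out, atol=1e-12)
        assert l == pytest.approx(length, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(vec3)
    def test_idempotent_and_contractive(self, v):
        n = np.array([0.6, 0.0, 0.8])
        w, l = project_vector_onto_plane(v, n)
        w2, l2 = project_vector_onto_plane(w, n)
        assert np.allclose(w, w2, atol=1e-9)
        assert l <= np.linalg.norm(v) + 1e-12


class TestRigidTransform:
    def test_rejects_reflection_and_skew(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) + 0.1, np.zeros(3))


class TestClosestPointOnTriangles:
    def test_matches_dense_surface_sampling(self):
        rng = np.random.default_rng(3)
        tri = rng.normal(size=(40, 3, 3)) * 3.0
        # dense barycentric sampling as a brute-force oracle
        u = np.linspace(0, 1, 60)
        uu, vv = np.meshgrid(u, u)
        keep = uu + vv <= 1.0
        bary = np.stack([1 - uu[keep] - vv[keep], uu[keep], vv[keep]], axis=1)
        samples = np.einsum("sk,nkj->nsj", bary, tri).reshape(-1, 3)
        for _ in range(10):
            q = rng.normal(size=3) * 4.0
            p, d = closest_point_on_triangles(tri, q)
            brute = np.linalg.norm(samples - q, axis=1).min()
            assert d <= brute + 1e-9
            assert abs(d - brute) < 0.05
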