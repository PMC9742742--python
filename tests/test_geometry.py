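"""Rigid-pose algebra, angle primitives, plane fitting, registration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from orthotrack.geometry import (
    GeometryError,
    InvalidPoseError,
    Plane,
    RigidPose,
    angle_between,
    compose,
    fit_plane,
    project_onto_plane,
    register_point_sets,
    signed_angle_in_plane,
    unit,
    vector_plane_angle,
)


def random_pose(rng):
    return RigidPose.random(rng)


class TestRigidPose:
    def test_identity_composition(self):
        e = RigidPose.identity()
        c = compose(e, e)
        assert np.allclose(c.quaternion, e.quaternion)
        assert np.allclose(c.translation, 0)

    def test_inverse_law(self, rng):
        for _ in range(20):
            p = random_pose(rng)
            r = compose(p, p.inverse())
            assert abs(r.quaternion[0]) > 1 - 1e-9
            assert np.linalg.norm(r.translation) < 1e-9

    def test_composition_matches_sequential_application(self, rng):
        """compose(p1, p2) applied to points == apply p2 then p1 (brute force)."""
        for _ in range(10):
            p1, p2 = random_pose(rng), random_pose(rng)
            pts = rng.uniform(-1, 1, size=(10, 3))
            direct = compose(p1, p2).apply(pts)
            sequential = p1.apply(p2.apply(pts))
            assert np.max(np.abs(direct - sequential)) < 1e-9

    def test_round_trip_maps_points_to_themselves(self, rng):
        for _ in range(50):
            p = random_pose(rng)
            pts = rng.uniform(-1, 1, size=(5, 3))
            back = p.inverse().apply(p.apply(pts))
            assert np.max(np.abs(back - pts)) < 1e-9

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(InvalidPoseError):
            RigidPose(np.array([1.0, 0.5, 0.0, 0.0]), np.zeros(3))

    def test_scalar_first_convention(self):
        """(w,x,y,z) = (cos45, sin45, 0, 0) is an active +90 deg turn about x."""
        h = np.sqrt(0.5)
        p = RigidPose(np.array([h, h, 0.0, 0.0]), np.zeros(3))
        assert np.allclose(p.apply([0.0, 1.0, 0.0]), [0.0, 0.0, 1.0], atol=1e-12)


class TestAngles:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 1, 0), (1, 0, 0), 45.0),
            ((1, 0, 0), (-1, 0, 0), 180.0),
        ],
    )
    def test_angle_between_examples(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-9)

    def test_angle_between_zero_vector_raises(self):
        with pytest.raises(GeometryError):
            angle_between((0, 0, 0), (1, 0, 0))

    def test_angle_between_matches_arccos_oracle(self, rng):
        for _ in range(1000):
            u = unit(rng.normal(size=3))
            v = unit(rng.normal(size=3))
            oracle = np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1)))
            assert abs(angle_between(u, v) - oracle) < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_plane_angle_complements_normal_angle(self, seed):
        """vector_plane_angle + angle to the normal = 90 for any unit vector."""
        r = np.random.default_rng(seed)
        u = unit(r.normal(size=3))
        n = unit(r.normal(size=3))
        pl = Plane(n)
        a = vector_plane_angle(u, pl)
        b = angle_between(u, n)
        assert abs(a + min(b, 180 - b) - 90.0) < 1e-9

    def test_vector_plane_angle_examples(self):
        pl = Plane((0, 0, 1))
        assert vector_plane_angle((0, 0, 1), pl) == pytest.approx(90.0)
        assert vector_plane_angle((1, 0, 0), pl) == pytest.approx(0.0)
        elevated = (np.cos(np.radians(30)), 0.0, np.sin(np.radians(30)))
        assert vector_plane_angle(elevated, pl) == pytest.approx(30.0, abs=1e-9)


class TestProjection:
    def test_in_plane_vector_unchanged(self):
        pl = Plane((0, 0, 1))
        assert np.allclose(project_onto_plane((1, 0, 0), pl), (1, 0, 0))

    def test_normal_projection_degenerate(self):
        with pytest.raises(GeometryError):
            project_onto_plane((0, 0, 1), Plane((0, 0, 1)))

    def test_projection_orthogonal_to_normal(self, rng):
        pl = Plane(unit(rng.normal(size=3)))
        for _ in range(100):
            u = unit(rng.normal(size=3))
            if abs(np.dot(u, pl.normal)) > 0.999:
                continue
            proj = project_onto_plane(u, pl)
            assert abs(np.dot(proj, pl.normal)) < 1e-12


class TestSignedAngle:
    def test_zero_for_equal_vectors(self):
        assert signed_angle_in_plane((1, 0, 0), (1, 0, 0), (0, 0, 1)) == 0.0

    def test_antisymmetric(self, rng):
        n = unit(rng.normal(size=3))
        u, v = unit(rng.normal(size=3)), unit(rng.normal(size=3))
        assert signed_angle_in_plane(u, v, n) == pytest.approx(
            -signed_angle_in_plane(v, u, n), abs=1e-9
        )

    def test_rotation_oracle(self, rng):
        """Rotating u by +25 deg about the normal gives a signed angle of 25."""
        for _ in range(20):
            n = unit(rng.normal(size=3))
            u = unit(rng.normal(size=3))
            if abs(np.dot(u, n)) > 0.99:
                continue
            v = Rotation.from_rotvec(np.radians(25.0) * n).apply(u)
            assert signed_angle_in_plane(u, v, n) == pytest.approx(25.0, abs=1e-9)


class TestFitPlane:
    def test_three_point_interpolation(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        pl = fit_plane(pts)
        assert np.allclose(np.abs(pl.normal), (0, 0, 1))
        assert max(abs(pl.signed_distance(p)) for p in pts) < 1e-12

    def test_collinear_points_raise(self):
        with pytest.raises(GeometryError):
            fit_plane([(0, 0, 0), (1, 0, 0), (2, 0, 0)])

    def test_hint_orients_normal(self):
        pl = fit_plane([(0, 0, 0), (1, 0, 0), (0, 1, 0)], hint=(0, 0, -1))
        assert np.allclose(pl.normal, (0, 0, -1))
        with pytest.raises(GeometryError):
            fit_plane([(0, 0, 0), (1, 0, 0), (0, 1, 0)], hint=(0.5, 0.5, 0))

    def test_noisy_coplanar_recovery(self, rng):
        """20 points with 0.1 mm noise: normal within 0.2 deg of truth."""
        true_n = unit([0.2, -0.3, 0.93])
        basis = np.linalg.svd(true_n.reshape(1, 3))[2][1:]
        coords = rng.uniform(-0.1, 0.1, size=(20, 2))
        pts = coords @ basis + rng.normal(0, 1e-4, size=(20, 3))
        pl = fit_plane(pts)
        err = angle_between(pl.normal, true_n)
        assert min(err, 180 - err) < 0.2


class TestRegistration:
    def test_identity_when_dst_equals_src(self, rng):
        src = rng.uniform(-0.1, 0.1, size=(6, 3))
        pose, rms = register_point_sets(src, src)
        assert rms < 1e-12
        assert abs(pose.quaternion[0]) > 1 - 1e-12
        assert np.linalg.norm(pose.translation) < 1e-12

    def test_exact_recovery_of_known_transform(self, rng):
        for _ in range(20):
            true = RigidPose.random(rng)
            src = rng.uniform(-0.2, 0.2, size=(8, 3))
            pose, rms = register_point_sets(src, true.apply(src))
            assert rms < 1e-9
            # quaternion dot >= 1 - 1e-12 up to sign
            assert abs(np.dot(pose.quaternion, true.quaternion)) >= 1 - 1e-12

    def test_noisy_rms_bounded(self, rng):
        sigma = 5e-4
        true = RigidPose.random(rng)
        src = rng.uniform(-0.2, 0.2, size=(6, 3))
        dst = true.apply(src) + rng.normal(0, sigma, size=(6, 3))
        _, rms = register_point_sets(src, dst)
        assert rms <= 3 * sigma

    def test_reflected_nonplanar_cloud_rejected(self, rng):
        src = rng.uniform(-0.1, 0.1, size=(6, 3))
        mirrored = src * np.array([1.0, 1.0, -1.0])
        with pytest.raises(GeometryError):
            register_point_sets(src, mirrored)

    def test_planar_cloud_still_yields_proper_rotation(self, rng):
        src = np.column_stack([rng.uniform(-0.1, 0.1, size=(5, 2)), np.zeros(5)])
        pose, rms = register_point_sets(src, src * np.array([1.0, -1.0, 1.0]))
        assert np.linalg.det(pose.rotation.as_matrix()) == pytest.approx(1.0)
        assert rms < 1e-9  # in-plane mirror of a planar cloud is a rotation

    @pytest.mark.parametrize(
        "src, dst",
        [
            ([(0, 0, 0), (1, 0, 0)], [(0, 0, 0), (1, 0, 0)]),
            ([(0, 0, 0), (1, 0, 0), (2, 0, 0)], [(0, 0, 0), (1, 0, 0), (2, 0, 0)]),
        ],
    )
    def test_degenerate_sets_raise(self, src, dst):
        with pytest.raises(GeometryError):
            register_point_sets(src, dst)
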