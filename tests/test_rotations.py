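"""Quaternion algebra, strapdown integration, and orientation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from swingtrack.rotations import (
    from_axis_angle,
    integrate_gyro,
    matrix_to_quat,
    mean_quaternion,
    quat_angle_error,
    quat_canonical,
    quat_conjugate,
    quat_distance_loss,
    quat_normalize,
    quat_product,
    quat_to_matrix,
    rotate_vector,
)

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def random_quat(rng, n=None):
    q = rng.normal(size=(n, 4) if n else 4)
    return quat_normalize(q)


class TestQuatProduct:
    def test_identity_and_inverse(self, rng):
        q = random_quat(rng)
        assert np.allclose(quat_product(IDENTITY, q), q)
        assert np.allclose(quat_product(q, quat_conjugate(q)), IDENTITY, atol=1e-12)

    def test_matches_rotation_matrix_composition(self, rng):
        # oracle: compose the two rotation matrices, convert back
        a = from_axis_angle([1, 0, 0], np.pi / 2)
        b = from_axis_angle([0, 1, 0], np.pi / 2)
        expected = matrix_to_quat(quat_to_matrix(a) @ quat_to_matrix(b))
        assert np.allclose(quat_canonical(quat_product(a, b)), expected, atol=1e-12)
        for _ in range(20):
            a, b = random_quat(rng), random_quat(rng)
            expected = matrix_to_quat(quat_to_matrix(a) @ quat_to_matrix(b))
            got = quat_canonical(quat_product(a, b))
            assert np.allclose(got, expected, atol=1e-10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            quat_product(np.array([np.nan, 0, 0, 0]), IDENTITY)


class TestRotateVector:
    def test_identity_and_axis_rotation(self):
        assert np.allclose(rotate_vector(IDENTITY, [1.0, 2.0, 3.0]), [1, 2, 3])
        q90z = from_axis_angle([0, 0, 1], np.pi / 2)
        assert np.allclose(rotate_vector(q90z, [1.0, 0, 0]), [0, 1, 0], atol=1e-12)

    def test_matches_sandwich_product(self, rng):
        # oracle: q (x) (0, v) (x) q* evaluated term by term
        for _ in range(20):
            q = random_quat(rng)
            v = rng.normal(size=3)
            pure = np.concatenate([[0.0], v])

            def raw(a, b):
                aw, ax, ay, az = a
                bw, bx, by, bz = b
                return np.array([
                    aw * bw - ax * bx - ay * by - az * bz,
                    aw * bx + ax * bw + ay * bz - az * by,
                    aw * by - ax * bz + ay * bw + az * bx,
                    aw * bz + ax * by - ay * bx + az * bw,
                ])

            expected = raw(raw(q, pure), quat_conjugate(q))[1:]
            assert np.allclose(rotate_vector(q, v), expected, atol=1e-12)

    def test_norm_preserving(self, rng):
        q = random_quat(rng)
        v = rng.normal(size=3)
        assert np.isclose(np.linalg.norm(rotate_vector(q, v)), np.linalg.norm(v))


class TestIntegrateGyro:
    def test_zero_rate_is_constant(self, rng):
        q0 = random_quat(rng)
        series = integrate_gyro(q0, np.zeros((50, 3)), 0.005)
        assert np.allclose(series.quaternions, q0)

    def test_empty_gyro_returns_initial(self):
        series = integrate_gyro(IDENTITY, np.zeros((0, 3)), 0.005)
        assert len(series) == 1
        assert np.allclose(series.quaternions[0], IDENTITY)

    def test_constant_rate_closed_form(self):
        # pi rad/s about z for 1 s at 200 Hz -> 180 deg rotation
        gyro = np.tile([0.0, 0.0, np.pi], (201, 1))
        series = integrate_gyro(IDENTITY, gyro, 1 / 200)
        expected = from_axis_angle([0, 0, 1], np.pi)
        err = np.rad2deg(quat_angle_error(series.quaternions[-1], expected))
        assert err < 0.1

    def test_two_segment_composition(self):
        # oracle: product of the two closed-form rotations
        dt = 1 / 400
        w1, w2 = np.array([2.0, 0, 0]), np.array([0, 0, -1.5])
        # sample k advances q_k -> q_{k+1}: exactly 200 steps per segment
        gyro = np.vstack([np.tile(w1, (200, 1)), np.tile(w2, (201, 1))])
        series = integrate_gyro(IDENTITY, gyro, dt)
        expected = quat_product(
            from_axis_angle(w1, np.linalg.norm(w1) * 0.5),
            from_axis_angle(w2, np.linalg.norm(w2) * 0.5),
        )
        err = np.rad2deg(quat_angle_error(series.quaternions[-1], expected))
        assert err < 0.2

    def test_halving_dt_reduces_error(self):
        expected = from_axis_angle([0, 1, 0], 4.0)
        errs = []
        for n in (100, 200):
            gyro = np.tile([0.0, 4.0, 0.0], (n + 1, 1))
            series = integrate_gyro(IDENTITY, gyro, 1.0 / n)
            errs.append(quat_angle_error(series.quaternions[-1], expected))
        assert errs[1] < errs[0]

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            integrate_gyro(IDENTITY, np.zeros((3, 3)), 0.0)


class TestAngleError:
    def test_basic_cases(self, rng):
        q = random_quat(rng)
        assert quat_angle_error(q, q) < 1e-12
        assert quat_angle_error(q, -q) < 1e-12  # sign invariance
        q90x = from_axis_angle([1, 0, 0], np.pi / 2)
        assert np.isclose(quat_angle_error(IDENTITY, q90x), np.pi / 2)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a, b = random_quat(rng), random_quat(rng)
            e1, e2 = quat_angle_error(a, b), quat_angle_error(b, a)
            assert np.isclose(e1, e2)
            assert 0 <= e1 <= np.pi + 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(-np.pi + 1e-6, np.pi - 1e-6))
    def test_recovers_axis_angle(self, angle):
        q = from_axis_angle([0.36, -0.48, 0.8], angle)
        assert np.isclose(quat_angle_error(IDENTITY, q), abs(angle), atol=1e-9)


class TestDistanceLoss:
    def test_same_rotation_is_zero(self, rng):
        q = random_quat(rng)
        assert quat_distance_loss(q, q) < 1e-12
        assert quat_distance_loss(q, -q) < 1e-12

    def test_orthogonal_is_one(self):
        q180 = from_axis_angle([0, 1, 0], np.pi)
        assert np.isclose(quat_distance_loss(IDENTITY, q180), 1.0)

    def test_relation_to_angle(self, rng):
        # loss = 1 - |cos(theta/2)|
        for _ in range(20):
            a, b = random_quat(rng), random_quat(rng)
            loss = quat_distance_loss(a, b)
            theta = quat_angle_error(a, b)
            assert np.isclose(loss, 1 - abs(np.cos(theta / 2)), atol=1e-10)


class TestMeanQuaternion:
    def test_constant_input(self, rng):
        q = quat_canonical(random_quat(rng))
        qs = np.tile(q, (7, 1))
        assert np.allclose(mean_quaternion(qs), q, atol=1e-12)

    def test_double_cover(self, rng):
        q = random_quat(rng)
        m = mean_quaternion(np.stack([q, -q]))
        assert quat_angle_error(m, q) < 1e-9

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mean_quaternion(np.empty((0, 4)))

    def test_perturbed_cluster_near_grid_minimizer(self, rng):
        # oracle: brute-force minimizer of the summed squared angle error
        # over a fine 1D geodesic grid through the eigenvector solution
        q0 = from_axis_angle([0.2, 0.5, 0.9], 1.1)
        qs = []
        for _ in range(25):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            pert = from_axis_angle(axis, np.deg2rad(rng.uniform(-5, 5)))
            qs.append(quat_canonical(quat_product(pert, q0)))
        qs = np.array(qs)
        m = mean_quaternion(qs)
        assert np.rad2deg(quat_angle_error(m, q0)) < 5.0

        def cost(q):
            return np.sum(quat_angle_error(np.tile(q, (len(qs), 1)), qs) ** 2)

        # brute-force search over small rotations around the eigen solution:
        # the grid minimizer must sit within 0.5 deg of it
        best_q, best_c = m, cost(m)
        for axis in np.eye(3):
            for ang in np.deg2rad(np.linspace(-3, 3, 121)):
                cand = quat_product(from_axis_angle(axis, ang), m)
                c = cost(cand)
                if c < best_c:
                    best_q, best_c = cand, c
        assert np.rad2deg(quat_angle_error(best_q, m)) < 0.5


class TestConversions:
    def test_matrix_round_trip(self, rng):
        qs = random_quat(rng, 50)
        back = matrix_to_quat(quat_to_matrix(qs))
        assert np.max(quat_angle_error(back, qs)) < 1e-9

    def test_matches_scipy(self, rng):
        q = random_quat(rng)
        ours = quat_to_matrix(q)
        theirs = Rotation.from_quat(np.roll(q, -1)).as_matrix()  # scipy is xyzw
        assert np.allclose(ours, theirs, atol=1e-12)
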