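"""Rigid transform algebra and the closed-form landmark fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fdctreg import (LandmarkError, LandmarkPairSet, RigidTransform3D, apply,
                     compose, fit_landmarks, invert)
from fdctreg.io import read_transform, write_transform
from fdctreg.transforms import params_to_transform, transform_to_params

from conftest import random_rigid


class TestApply:
    def test_identity_and_translation(self):
        assert np.allclose(apply(RigidTransform3D.identity(), [4, 5, 6]), [4, 5, 6])
        T = RigidTransform3D(np.eye(3), [1, 2, 3])
        assert np.allclose(apply(T, [0, 0, 0]), [1, 2, 3])

    def test_quarter_turn_about_z(self):
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        T = RigidTransform3D(Rz, np.zeros(3))
        assert np.allclose(apply(T, [1, 0, 0]), [0, 1, 0], atol=1e-12)

    def test_rotation_center_is_fixed_point(self, rng):
        T = random_rigid(rng, max_shift=0.0)
        assert np.allclose(apply(T, T.center), T.center, atol=1e-12)

    def test_distances_preserved(self, rng):
        pts = rng.normal(0, 30, (40, 3))
        for _ in range(20):
            T = random_rigid(rng)
            q = apply(T, pts)
            d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            d1 = np.linalg.norm(q[:, None] - q[None, :], axis=-1)
            assert np.allclose(d0, d1, atol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform3D(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestComposeInvert:
    def test_inverse_composes_to_identity(self, rng):
        T = random_rigid(rng)
        C = compose(T, invert(T))
        pts = rng.normal(0, 20, (30, 3))
        assert np.allclose(apply(C, pts), pts, atol=1e-9)

    def test_translations_add(self):
        a = RigidTransform3D(np.eye(3), [1, 0, 0])
        b = RigidTransform3D(np.eye(3), [0, 2, 0])
        c = compose(a, b)
        assert np.allclose(apply(c, [0, 0, 0]), [1, 2, 0], atol=1e-12)

    def test_compose_matches_sequential_application(self, rng):
        for _ in range(10):
            a, b = random_rigid(rng), random_rigid(rng)
            pts = rng.normal(0, 25, (50, 3))
            assert np.allclose(apply(compose(a, b), pts), apply(a, apply(b, pts)), atol=1e-9)

    def test_invert_round_trips_points(self, rng):
        T = random_rigid(rng)
        pts = rng.normal(0, 40, (200, 3))
        assert np.allclose(apply(invert(T), apply(T, pts)), pts, atol=1e-9)
        assert np.allclose(apply(invert(RigidTransform3D(np.eye(3), [3, -1, 2])), [0, 0, 0]),
                           [-3, 1, -2], atol=1e-12)


def _rss(params, F, M):
    T = params_to_transform(params, F.mean(axis=0))
    return float(np.sum((apply(T, F) - M) ** 2))


class TestLandmarkFit:
    def test_identical_points_give_identity(self):
        F = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
        T = fit_landmarks(LandmarkPairSet(F, F))
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(apply(T, F), F, atol=1e-12)

    def test_exact_recovery_of_known_transform(self, rng):
        F = np.array([[0, 0, 0], [20, 0, 5], [3, 15, -2]], dtype=float)
        for _ in range(10):
            T = random_rigid(rng, max_angle=0.5, max_shift=20)
            fit = fit_landmarks(LandmarkPairSet(F, apply(T, F)))
            assert np.allclose(apply(fit, F), apply(T, F), atol=1e-9)
            Ra, ba = T.as_affine()
            Rb, bb = fit.as_affine()
            assert np.allclose(Ra, Rb, atol=1e-9)
            assert np.allclose(ba, bb, atol=1e-9)

    def test_noisy_fit_beats_numeric_search(self, rng):
        F = rng.normal(0, 15, (4, 3))
        T = random_rigid(rng, max_angle=0.3, max_shift=10, center=F.mean(axis=0))
        M = apply(T, F) + rng.normal(0, 0.5, (4, 3))
        fit = fit_landmarks(LandmarkPairSet(F, M))
        rss_fit = float(np.sum((apply(fit, F) - M) ** 2))
        # independent numeric search over the 6 parameters
        best = np.inf
        for _ in range(10):
            p0 = transform_to_params(T, F.mean(axis=0)) + rng.normal(0, 0.1, 6)
            res = minimize(_rss, p0, args=(F, M), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, res.fun)
        assert rss_fit <= best + 1e-9

    def test_equivariance_under_common_rotation(self, rng):
        F = rng.normal(0, 15, (5, 3))
        M = apply(random_rigid(rng, max_angle=0.4, max_shift=10), F) + rng.normal(0, 0.3, (5, 3))
        Q = random_rigid(rng)
        T = fit_landmarks(LandmarkPairSet(F, M))
        Tq = fit_landmarks(LandmarkPairSet(apply(Q, F), apply(Q, M)))
        assert np.allclose(apply(Tq, apply(Q, F)), apply(Q, apply(T, F)), atol=1e-8)

    def test_never_produces_reflection(self, rng):
        # near-planar, noisy configurations tempt the SVD into det=-1
        for _ in range(20):
            F = rng.normal(0, 10, (4, 3)) * [1, 1, 0.01]
            M = -F[:, [1, 0, 2]] + rng.normal(0, 3, (4, 3))
            fit = fit_landmarks(LandmarkPairSet(F, M))
            assert np.linalg.det(fit.rotation) > 0.999999

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(LandmarkError, match="collinear"):
            fit_landmarks(LandmarkPairSet(line, line + 1))
        two = np.zeros((2, 3))
        with pytest.raises(LandmarkError, match="3"):
            fit_landmarks(LandmarkPairSet(two, two))
        with pytest.raises(LandmarkError, match="differ"):
            LandmarkPairSet(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_cross_validation_against_simpleitk(self, rng):
        sitk = pytest.importorskip("SimpleITK")
        F = np.array([[0, 0, 0], [20, 0, 5], [3, 15, -2], [-5, 4, 12]], dtype=float)
        T = random_rigid(rng, max_angle=0.4, max_shift=15)
        M = apply(T, F) + rng.normal(0, 0.4, F.shape)
        ours = fit_landmarks(LandmarkPairSet(F, M))
        ref = sitk.LandmarkBasedTransformInitializer(
            sitk.VersorRigid3DTransform(),
            list(F.ravel()), list(M.ravel()))
        probe = rng.normal(0, 20, (25, 3))
        theirs = np.array([ref.TransformPoint(p) for p in probe])
        assert np.allclose(apply(ours, probe), theirs, atol=1e-4)


class TestParameterization:
    def test_params_round_trip(self, rng):
        center = rng.normal(0, 10, 3)
        p = np.concatenate([rng.uniform(-0.3, 0.3, 3), rng.uniform(-20, 20, 3)])
        T = params_to_transform(p, center)
        assert np.allclose(transform_to_params(T, center), p, atol=1e-12)

    def test_euler_convention_is_zyx(self):
        p = np.array([0.1, -0.2, 0.3, 0, 0, 0])
        T = params_to_transform(p, np.zeros(3))
        expected = (Rotation.from_euler("z", 0.3) * Rotation.from_euler("y", -0.2)
                    * Rotation.from_euler("x", 0.1)).as_matrix()
        assert np.allclose(T.rotation, expected, atol=1e-12)


finite = lambda lo, hi: st.floats(lo, hi, allow_nan=False, allow_infinity=False)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(params=st.tuples(*[finite(-1.0, 1.0)] * 3, *[finite(-30.0, 30.0)] * 3),
       center=st.tuples(*[finite(-20.0, 20.0)] * 3))
def test_rigid_action_preserves_distances_property(params, center):
    """Any parameterized rigid transform is an isometry, and the 6-vector
    parameterization round-trips away from gimbal lock."""
    T = params_to_transform(np.array(params), np.array(center))
    pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [3, 4, 5]], dtype=float)
    q = apply(T, pts)
    d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d1 = np.linalg.norm(q[:, None] - q[None, :], axis=-1)
    assert np.allclose(d0, d1, atol=1e-9)
    assert np.allclose(transform_to_params(T, np.array(center)), params, atol=1e-9)


def test_transform_text_round_trip(tmp_path, rng):
    T = random_rigid(rng)
    write_transform(T, tmp_path / "t.txt")
    back = read_transform(tmp_path / "t.txt")
    assert np.array_equal(back.rotation, T.rotation)
    assert np.array_equal(back.translation, T.translation)
    assert np.array_equal(back.center, T.center)
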