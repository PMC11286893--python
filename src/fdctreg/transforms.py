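"""Rigid 3D transforms and landmark sets.

A rigid transform is a rotation about a center plus a translation,

    T(p) = R (p - c) + c + t,

with R a proper rotation (R Rᵀ = I, det R = +1).  Rigid maps are all the
geometry the CT/FDCT alignment problem allows: the skull and the implanted
electrode move as one rigid body between the two acquisitions, so neither
scaling nor shear is modelled.

The landmark fit is the closed-form least-squares (Kabsch/Umeyama) solution:
given >= 3 corresponding point pairs it returns the rigid transform
minimizing the sum of squared distances between mapped fixed points and
their moving correspondents, with the reflection-corrected SVD rotation and
the rotation center placed at the centroid of the fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import LandmarkError

__all__ = [
    "RigidTransform3D",
    "LandmarkPairSet",
    "apply",
    "compose",
    "invert",
    "fit_landmarks",
    "params_to_transform",
    "transform_to_params",
]

_RIGID_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform3D:
    """6-parameter rotation + translation acting on physical points (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix must not contain a reflection (det must be +1)")

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_affine(cls, R: np.ndarray, b: np.ndarray, center=None) -> "RigidTransform3D":
        """Build from the affine form T(p) = R p + b, re-expressed about ``center``."""
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        t = np.asarray(b, dtype=float) - c + np.asarray(R) @ c
        return cls(R, t, c)

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (R, b) with T(p) = R p + b."""
        b = self.center + self.translation - self.rotation @ self.center
        return self.rotation, b

    def __call__(self, p):
        return apply(self, p)


def apply(T: RigidTransform3D, p) -> np.ndarray:
    """Apply T to one point (3,) or many points (..., 3)."""
    p = np.asarray(p, dtype=float)
    return (p - T.center) @ T.rotation.T + T.center + T.translation


def compose(outer: RigidTransform3D, inner: RigidTransform3D) -> RigidTransform3D:
    """The rigid transform p -> outer(inner(p))."""
    Ro, bo = outer.as_affine()
    Ri, bi = inner.as_affine()
    return RigidTransform3D.from_affine(Ro @ Ri, Ro @ bi + bo, center=inner.center)


def invert(T: RigidTransform3D) -> RigidTransform3D:
    """The rigid transform with invert(T)(T(p)) = p."""
    R, b = T.as_affine()
    return RigidTransform3D.from_affine(R.T, -R.T @ b, center=T.center)


@dataclass
class LandmarkPairSet:
    """Ordered corresponding physical points in fixed and moving spaces."""

    fixed_points: np.ndarray
    moving_points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.fixed_points = np.asarray(self.fixed_points, dtype=float).reshape(-1, 3)
        self.moving_points = np.asarray(self.moving_points, dtype=float).reshape(-1, 3)
        if len(self.fixed_points) != len(self.moving_points):
            raise LandmarkError(
                f"fixed and moving point counts differ: "
                f"{len(self.fixed_points)} vs {len(self.moving_points)}"
            )
        if self.labels is not None and len(self.labels) != len(self.fixed_points):
            raise LandmarkError("label count does not match point count")

    def __len__(self) -> int:
        return len(self.fixed_points)


def fit_landmarks(pairs: LandmarkPairSet) -> RigidTransform3D:
    """Closed-form least-squares rigid fit mapping fixed points onto moving points.

    Requires >= 3 pairs whose fixed points are not (near-)collinear.  The
    rotation comes from the SVD of the cross-covariance of the centered
    point sets with the standard det-correction, so the result never
    contains a reflection.  The rotation center is the fixed centroid.
    """
    F = pairs.fixed_points
    M = pairs.moving_points
    n = len(F)
    if n < 3:
        raise LandmarkError(f"rigid initialization needs at least 3 pairs, got {n}")
    cf = F.mean(axis=0)
    cm = M.mean(axis=0)
    Fc = F - cf
    Mc = M - cm
    sv = np.linalg.svd(Fc, compute_uv=False)
    if sv[1] <= 1e-6 * sv[0]:
        raise LandmarkError("fixed landmarks are collinear or coincident; rotation is underdetermined")
    H = Fc.T @ Mc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform3D(R, cm - cf, center=cf)


# ---------------------------------------------------------------------------
# 6-vector parameterization used by the optimizer: ZYX Euler angles (radians)
# about a fixed rotation center, then translations (mm).
# ---------------------------------------------------------------------------

def params_to_transform(p, center) -> RigidTransform3D:
    """(ax, ay, az, tx, ty, tz) -> rigid transform with R = Rz(az) Ry(ay) Rx(ax)."""
    p = np.asarray(p, dtype=float).reshape(6)
    R = Rotation.from_euler("ZYX", [p[2], p[1], p[0]]).as_matrix()
    return RigidTransform3D(R, p[3:6], center=np.asarray(center, dtype=float))


def transform_to_params(T: RigidTransform3D, center) -> np.ndarray:
    """Inverse of :func:`params_to_transform` (re-centers T about ``center``)."""
    center = np.asarray(center, dtype=float)
    R, b = T.as_affine()
    az, ay, ax = Rotation.from_matrix(R).as_euler("ZYX")
    t = b - center + R @ center
    return np.array([ax, ay, az, *t])
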