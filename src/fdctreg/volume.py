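"""Physical-space 3D volume model.

A :class:`Volume3D` couples a scalar voxel grid with the geometry needed to
place every voxel in patient (LPS) physical space: spacing in mm, the physical
position of the first voxel's *center* (origin), and a 3x3 orthonormal
direction matrix whose columns are the axis direction cosines.  Voxel indices
are 0-based and continuous indices follow the voxel-center convention, so the
index->physical map is the affine

    p = origin + direction @ (spacing * index)

The voxel array is indexed ``data[ix, iy, iz]``, i.e. ``data.shape == size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = ["Volume3D", "index_to_physical", "physical_to_index"]

_ORTHO_TOL = 1e-6


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with physical geometry.

    Parameters
    ----------
    data:
        3D array of intensities, indexed ``data[ix, iy, iz]``.
    spacing:
        Voxel edge lengths in mm, all positive.
    origin:
        Physical position (mm, LPS) of the center of voxel (0, 0, 0).
    direction:
        3x3 orthonormal matrix with determinant +1; columns are the
        direction cosines of the voxel axes.  Defaults to identity.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=_ORTHO_TOL):
            raise GeometryError("direction matrix is not orthonormal")
        if abs(np.linalg.det(self.direction) - 1.0) > _ORTHO_TOL:
            raise GeometryError("direction matrix must have determinant +1")

    @property
    def size(self) -> tuple[int, int, int]:
        """Grid extent in voxels per axis."""
        return self.data.shape  # type: ignore[return-value]

    @property
    def physical_center(self) -> np.ndarray:
        """Physical point at the center of the grid."""
        mid = (np.array(self.size, dtype=float) - 1.0) / 2.0
        return index_to_physical(self, mid)

    def same_geometry(self, other: "Volume3D", tol: float = 1e-9) -> bool:
        """True if both volumes share size, spacing, origin and direction."""
        return (
            self.size == other.size
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def copy_with(self, data: np.ndarray) -> "Volume3D":
        """New volume with the same geometry and different voxel data."""
        return Volume3D(data, self.spacing.copy(), self.origin.copy(), self.direction.copy())


def index_to_physical(vol: Volume3D, idx) -> np.ndarray:
    """Map continuous voxel indices to physical points (mm).

    ``idx`` may be a single 3-vector or an (..., 3) array; indices may lie
    outside the grid (the map is a total affine).
    """
    idx = np.asarray(idx, dtype=float)
    return vol.origin + (idx * vol.spacing) @ vol.direction.T


def physical_to_index(vol: Volume3D, p) -> np.ndarray:
    """Exact inverse of :func:`index_to_physical`."""
    p = np.asarray(p, dtype=float)
    return ((p - vol.origin) @ vol.direction) / vol.spacing
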