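"""Trilinear sampling, grid-to-grid resampling and display rescaling.

Resampling evaluates the moving image at each target voxel center mapped
through the fixed->moving transform, so the output occupies exactly the
requested grid.  Interpolation is trilinear; points within the half-voxel
boundary shell clamp to edge voxels, points beyond it take a default value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FdctRegError
from .transforms import RigidTransform3D, apply
from .volume import Volume3D, index_to_physical, physical_to_index

__all__ = [
    "ResamplePlan",
    "trilinear_sample",
    "sample_volume",
    "resample_to_grid",
    "rescale_0_255",
]


@dataclass
class ResamplePlan:
    """Target grid geometry for resampling, plus the out-of-bounds intensity."""

    size: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    default_value: float = 0.0

    @classmethod
    def like(cls, vol: Volume3D, default_value: float = 0.0) -> "ResamplePlan":
        """A plan matching an existing volume's grid."""
        return cls(vol.size, vol.spacing.copy(), vol.origin.copy(),
                   vol.direction.copy(), default_value)

    def empty_volume(self) -> Volume3D:
        return Volume3D(np.zeros(self.size), self.spacing, self.origin, self.direction)


def sample_volume(vol: Volume3D, points, default: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear-sample ``vol`` at physical ``points`` ((..., 3)).

    Returns ``(values, inside)`` where ``inside`` marks points whose
    continuous index lies in [-0.5, size-0.5) on every axis; outside points
    get ``default``.
    """
    points = np.asarray(points, dtype=float)
    idx = physical_to_index(vol, points)
    size = np.array(vol.size)
    inside = np.all((idx >= -0.5) & (idx < size - 0.5), axis=-1)

    idxc = np.clip(idx, 0.0, size - 1.0)
    i0 = np.floor(idxc).astype(np.intp)
    i0 = np.minimum(i0, np.maximum(size - 2, 0))
    i1 = np.minimum(i0 + 1, size - 1)
    f = idxc - i0

    d = vol.data
    x0, y0, z0 = i0[..., 0], i0[..., 1], i0[..., 2]
    x1, y1, z1 = i1[..., 0], i1[..., 1], i1[..., 2]
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz

    vals = (
        d[x0, y0, z0] * gx * gy * gz
        + d[x1, y0, z0] * fx * gy * gz
        + d[x0, y1, z0] * gx * fy * gz
        + d[x0, y0, z1] * gx * gy * fz
        + d[x1, y1, z0] * fx * fy * gz
        + d[x1, y0, z1] * fx * gy * fz
        + d[x0, y1, z1] * gx * fy * fz
        + d[x1, y1, z1] * fx * fy * fz
    )
    vals = np.where(inside, vals, default)
    return vals, inside


def trilinear_sample(vol: Volume3D, p, default: float = 0.0):
    """Trilinear interpolation of the volume at physical point(s) ``p``."""
    vals, _ = sample_volume(vol, p, default)
    return vals


def resample_to_grid(moving: Volume3D, plan: ResamplePlan,
                     T: RigidTransform3D | None = None) -> Volume3D:
    """Sample ``moving`` through ``T`` (fixed->moving map) onto the plan's grid.

    Output voxel at physical center p holds the trilinear sample of
    ``moving`` at T(p); the output geometry equals the plan exactly.
    """
    if T is None:
        T = RigidTransform3D.identity()
    out_vol = plan.empty_volume()
    nx, ny, nz = plan.size
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    out = np.empty(plan.size, dtype=float)
    # slab-by-slab keeps peak memory flat for clinical-scale grids
    for iz in range(nz):
        idx = np.stack([ix, iy, np.full_like(ix, iz)], axis=-1)
        p = index_to_physical(out_vol, idx)
        out[:, :, iz], _ = sample_volume(moving, apply(T, p), plan.default_value)
    return Volume3D(out, plan.spacing, plan.origin, plan.direction)


def rescale_0_255(vol: Volume3D, window_low: float, window_high: float) -> Volume3D:
    """Window the intensities and map them linearly to [0, 255] (float).

    Values at or below ``window_low`` map to 0, at or above ``window_high``
    to 255 — the display normalization applied before fusing CT and FDCT,
    whose native ranges differ grossly.
    """
    if not window_high > window_low:
        raise FdctRegError(
            f"degenerate intensity window: low={window_low}, high={window_high}"
        )
    scaled = (vol.data.astype(float) - window_low) / (window_high - window_low)
    return vol.copy_with(np.clip(scaled, 0.0, 1.0) * 255.0)
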