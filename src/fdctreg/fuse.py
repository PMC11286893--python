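"""Fusion renderers for qualitative assessment of a registration.

All renderers require the two volumes to share one grid (resample the
moving image onto the fixed grid first).  Checkerboard interleaves
alternating tiles of the inputs; alpha blending mixes them linearly;
cut-out fusion shows the narrow-FOV FDCT wherever it carries signal and
the CT elsewhere, which restores anatomical context around the electrode.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryMismatchError
from .transforms import RigidTransform3D, apply
from .volume import Volume3D, index_to_physical, physical_to_index

__all__ = ["checkerboard", "alpha_blend", "cutout_fuse", "linked_cursor"]


def _check_geometry(a: Volume3D, b: Volume3D) -> None:
    if not a.same_geometry(b):
        raise GeometryMismatchError(
            "volumes do not share a grid; resample the moving image onto the "
            "fixed grid before fusing")


def _tile_parity(n: int, tiles: int) -> np.ndarray:
    """Tile index along one axis; leading tiles absorb the remainder voxels."""
    tiles = min(tiles, n)
    base, rem = divmod(n, tiles)
    sizes = np.full(tiles, base)
    sizes[:rem] += 1
    return np.repeat(np.arange(tiles), sizes)


def checkerboard(a: Volume3D, b: Volume3D, tiles=(8, 8, 1)) -> Volume3D:
    """Interleave a and b in an alternating 3D checkerboard pattern."""
    _check_geometry(a, b)
    if any(t < 1 for t in tiles):
        raise ValueError(f"tile counts must be >= 1, got {tiles}")
    tx = _tile_parity(a.size[0], tiles[0])
    ty = _tile_parity(a.size[1], tiles[1])
    tz = _tile_parity(a.size[2], tiles[2])
    parity = (tx[:, None, None] + ty[None, :, None] + tz[None, None, :]) % 2
    return a.copy_with(np.where(parity == 0, a.data, b.data))


def alpha_blend(a: Volume3D, b: Volume3D, alpha: float = 0.5) -> Volume3D:
    """Voxelwise alpha*a + (1-alpha)*b; rescale inputs to 0-255 first."""
    _check_geometry(a, b)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return a.copy_with(alpha * a.data.astype(float) + (1.0 - alpha) * b.data.astype(float))


def cutout_fuse(ct: Volume3D, dctm_resampled: Volume3D, threshold: float = 0.0) -> Volume3D:
    """FDCT wherever its intensity exceeds ``threshold``, CT elsewhere."""
    _check_geometry(ct, dctm_resampled)
    return ct.copy_with(
        np.where(dctm_resampled.data > threshold, dctm_resampled.data, ct.data))


def linked_cursor(idx_a, a: Volume3D, b: Volume3D,
                  T: RigidTransform3D) -> tuple[np.ndarray, bool]:
    """Map a cursor position (continuous voxel index in ``a``) to the
    corresponding continuous index in ``b`` through the a->b physical map.

    Returns (index, inside) where ``inside`` is False when the point falls
    outside b's grid; display rounding is the caller's choice.
    """
    idx_b = physical_to_index(b, apply(T, index_to_physical(a, idx_a)))
    inside = bool(np.all((idx_b >= -0.5) & (idx_b < np.array(b.size) - 0.5)))
    return idx_b, inside
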