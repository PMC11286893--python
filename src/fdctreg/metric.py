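"""Joint-histogram mutual information between a fixed and a moving volume.

The similarity driving the multimodal alignment is discrete mutual
information in nats: intensities of randomly sampled fixed-grid voxel
centers are paired with trilinear samples of the moving image at the
transformed locations, binned into a 2D contingency table (50 bins per axis
by default, hard assignment, per-image min/max bin edges), and

    MI = sum_ij p_ij ln( p_ij / (p_i. p_.j) ),  0 ln 0 = 0.

MI peaks when one image's intensity predicts the other's, which is exactly
what holds at correct alignment of CT and FDCT despite their unrelated
intensity scales.  Sampling is uniform without replacement over fixed voxel
centers (1% by default) and fully determined by the seed; samples that map
outside the moving volume are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoOverlapError
from .resample import sample_volume
from .transforms import RigidTransform3D, apply
from .volume import Volume3D, index_to_physical

__all__ = [
    "MetricConfig",
    "JointHistogram",
    "joint_histogram",
    "mutual_information",
    "metric_value",
    "MIObjective",
]


@dataclass
class MetricConfig:
    """Tunables of the mutual-information metric.

    ``min_samples`` floors the drawn sample count so that small (desk-scale)
    grids still populate the histogram; it never raises the count above the
    number of fixed voxels, and full sampling is unaffected.
    """

    bins: int = 50
    sampling_fraction: float = 0.01
    seed: int = 0
    min_samples: int = 5000

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError(f"sampling_fraction must be in (0, 1], got {self.sampling_fraction}")


@dataclass
class JointHistogram:
    """2D contingency table of co-occurring fixed/moving intensity bins."""

    counts: np.ndarray
    fixed_edges: np.ndarray
    moving_edges: np.ndarray
    n_samples: int


def _edges(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # constant image: any single bin holds everything
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, bins + 1)


def _draw_sample_points(fixed: Volume3D, cfg: MetricConfig,
                        domain: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sampled fixed intensities and their physical positions.

    ``domain`` optionally restricts the draw to a subset of flat voxel
    indices (e.g. the fixed/moving overlap region at a descent's start).
    """
    pool = np.arange(fixed.data.size) if domain is None else np.asarray(domain)
    n_total = len(pool)
    if n_total < 1:
        raise ValueError("fixed volume has no sampleable voxels")
    n = int(round(cfg.sampling_fraction * fixed.data.size))
    n = min(n_total, max(n, min(cfg.min_samples, n_total), 1))
    rng = np.random.default_rng(cfg.seed)
    flat = pool if n == n_total else pool[rng.choice(n_total, size=n, replace=False)]
    idx = np.stack(np.unravel_index(flat, fixed.size), axis=-1)
    fvals = fixed.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    pts = index_to_physical(fixed, idx)
    return fvals, pts


def _histogram(fvals, mvals, bins) -> JointHistogram:
    fe = _edges(fvals, bins)
    me = _edges(mvals, bins)
    counts, _, _ = np.histogram2d(fvals, mvals, bins=[fe, me])
    return JointHistogram(counts, fe, me, int(len(fvals)))


def joint_histogram(fixed: Volume3D, moving: Volume3D, T: RigidTransform3D,
                    cfg: MetricConfig) -> JointHistogram:
    """Build the sampled joint intensity histogram at transform ``T``.

    ``T`` maps fixed-space physical points into moving space.  Raises
    :class:`NoOverlapError` when every sample lands outside the moving
    volume (a grossly wrong transform).
    """
    fvals, pts = _draw_sample_points(fixed, cfg)
    mvals, inside = sample_volume(moving, apply(T, pts))
    if not np.any(inside):
        raise NoOverlapError("all metric samples fall outside the moving volume")
    return _histogram(fvals[inside], mvals[inside], cfg.bins)


def mutual_information(h: JointHistogram) -> float:
    """Mutual information of the histogram, in nats (always >= 0)."""
    if h.n_samples <= 0:
        raise ValueError("empty joint histogram")
    p = h.counts / h.n_samples
    pf = p.sum(axis=1, keepdims=True)
    pm = p.sum(axis=0, keepdims=True)
    mask = p > 0
    outer = pf @ pm
    return float(np.sum(p[mask] * np.log(p[mask] / outer[mask])))


def metric_value(fixed: Volume3D, moving: Volume3D, T: RigidTransform3D,
                 cfg: MetricConfig) -> float:
    """MI of the sampled joint histogram — the optimizer's objective."""
    return mutual_information(joint_histogram(fixed, moving, T, cfg))


class MIObjective:
    """MI objective with a frozen sample set.

    The fixed-voxel sample is drawn once at construction so the objective is
    a smooth(er), deterministic function of the transform during one descent
    (one instance per resolution level).  Bin edges are still recomputed at
    every evaluation from the sampled intensities.

    When ``overlap_transform`` is given, the draw is restricted to fixed
    voxels that map inside the moving volume under that transform (the
    overlap region at the descent's start).  Without this restriction the
    sparse-sample MI estimate carries a positive bias that *grows* as the
    overlap shrinks, which rewards transforms that push the narrow-FOV
    moving image away; sampling the start-of-level overlap removes that
    spurious gradient.
    """

    def __init__(self, fixed: Volume3D, moving: Volume3D, cfg: MetricConfig,
                 overlap_transform: RigidTransform3D | None = None):
        self.moving = moving
        self.bins = cfg.bins
        domain = None
        if overlap_transform is not None:
            all_idx = np.stack(np.unravel_index(np.arange(fixed.data.size), fixed.size), axis=-1)
            centers = index_to_physical(fixed, all_idx)
            _, inside = sample_volume(moving, apply(overlap_transform, centers))
            domain = np.nonzero(inside)[0]
            if domain.size == 0:
                raise NoOverlapError(
                    "no fixed voxel maps inside the moving volume at the given transform")
        self._fvals, self._pts = _draw_sample_points(fixed, cfg, domain)

    def histogram(self, T: RigidTransform3D) -> JointHistogram:
        mvals, inside = sample_volume(self.moving, apply(T, self._pts))
        if not np.any(inside):
            raise NoOverlapError("all metric samples fall outside the moving volume")
        return _histogram(self._fvals[inside], mvals[inside], self.bins)

    def __call__(self, T: RigidTransform3D) -> float:
        return mutual_information(self.histogram(T))
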