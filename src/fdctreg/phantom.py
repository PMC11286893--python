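"""Synthetic CT/FDCT phantom pairs with known ground truth.

The generator emulates the study geometry at desk scale: a wide-FOV,
anisotropic CT grid covering an ellipsoidal skull shell with a brain-like
interior, and a narrow cylindrical-FOV isotropic FDCT grid centered on an
implanted DBS-electrode-like object whose lead level carries three
segmented contacts at 120 degree offsets.  The same analytic scene is
rasterized onto both grids, related by a randomly drawn rigid transform;
FDCT intensities additionally pass through a monotone nonlinear remap (a
gamma curve onto a 16-bit-like range) so that only statistical-dependence
metrics such as mutual information — not intensity difference — can align
the pair.  Independent Gaussian noise is added per modality.

Desk-scale default grids (CT 96x96x48 at 1.0x1.0x1.75 mm, FDCT 128^3 at
0.35 mm isotropic) preserve the clinical FOV and resolution *ratios*
(narrow isotropic FDCT inside a wide anisotropic CT) rather than the
absolute 512-matrix sizes; clinical-scale grids are available by spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import PhantomSpecError
from .transforms import (LandmarkPairSet, RigidTransform3D, apply, invert,
                         params_to_transform)
from .volume import Volume3D, index_to_physical

__all__ = ["PhantomSpec", "PhantomBundle", "make_phantom", "sample_transform",
           "write_bundle", "intensity_remap", "intensity_remap_inverse"]

# analytic scene intensities (HU-like arbitrary units; air is 0 so the
# resampling/out-of-FOV default of 0 reads as background)
AIR, BRAIN, SKULL, SHAFT, CONTACT = 0.0, 1000.0, 2000.0, 3000.0, 4000.0
_REMAP_SCALE = 30000.0  # FDCT 16-bit-like output range
_REMAP_GAMMA = 0.7
_EDGE_MM = 0.4  # smooth transition width of scene boundaries


@dataclass
class PhantomSpec:
    """Parameters of a matched CT/FDCT phantom pair."""

    ct_size: tuple = (96, 96, 48)
    ct_spacing_mm: tuple = (1.0, 1.0, 1.75)
    fdct_size: tuple = (128, 128, 128)
    fdct_spacing_mm: tuple = (0.35, 0.35, 0.35)
    skull_radii_mm: tuple = (34.0, 30.0, 26.0)
    skull_thickness_mm: float = 3.0
    shaft_radius_mm: float = 1.0
    shaft_length_mm: float = 60.0
    contact_radius_mm: float = 0.5
    contact_length_mm: float = 1.5
    contact_ring_radius_mm: float = 1.2
    contacts_per_level: int = 3  # directional-lead geometry
    contact_level_offset_mm: float = 3.0
    max_rotation_deg: tuple = (10.0, 10.0, 10.0)
    max_translation_mm: tuple = (15.0, 15.0, 15.0)
    landmark_noise_sd_mm: float = 0.0
    intensity_remap: str = "gamma"
    ct_noise_sd: float = 30.0
    fdct_noise_sd: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_spacing_mm", "fdct_spacing_mm", "skull_radii_mm"):
            if any(v <= 0 for v in getattr(self, name)):
                raise PhantomSpecError(f"{name} must be positive, got {getattr(self, name)}")
        if any(v < 1 for v in self.ct_size) or any(v < 1 for v in self.fdct_size):
            raise PhantomSpecError("grid sizes must be >= 1 voxel per axis")
        for name in ("skull_thickness_mm", "shaft_radius_mm", "shaft_length_mm",
                     "contact_radius_mm", "contact_length_mm", "contact_ring_radius_mm",
                     "contact_level_offset_mm"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be positive")
        if self.contacts_per_level != 3:
            raise PhantomSpecError("directional-lead geometry requires exactly 3 contacts per level")
        if self.intensity_remap not in ("gamma", "identity"):
            raise PhantomSpecError(f"unknown intensity remap {self.intensity_remap!r}")
        if any(v < 0 for v in self.max_rotation_deg) or any(v < 0 for v in self.max_translation_mm):
            raise PhantomSpecError("transform ranges must be non-negative")


@dataclass
class PhantomBundle:
    """A generated phantom pair with its ground truth and landmark sets."""

    ct: Volume3D
    fdct: Volume3D
    true_transform: RigidTransform3D  # CT physical space -> FDCT physical space
    init_pairs: LandmarkPairSet  # 3 pairs (moving copies optionally jittered)
    eval_pairs: LandmarkPairSet  # 5 exact held-out pairs


# ---------------------------------------------------------------------------
# analytic scene
# ---------------------------------------------------------------------------

def _smooth_in(d: np.ndarray, w: float = _EDGE_MM) -> np.ndarray:
    """1 deep inside (d << 0), 0 outside, linear ramp of width w."""
    return np.clip(0.5 - d / w, 0.0, 1.0)


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - a - t[..., None] * ab, axis=-1)


class _Scene:
    """The shared analytic scene, defined in CT physical coordinates."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        s = spec
        self.outer = np.array(s.skull_radii_mm)
        self.inner = self.outer - s.skull_thickness_mm
        if np.any(self.inner <= 0):
            raise PhantomSpecError("skull thickness exceeds skull radii")
        self.tip = np.array([6.0, 0.0, -2.0])
        d = np.array([0.25, 0.1, 0.96])
        self.axis = d / np.linalg.norm(d)
        self.shaft_end = self.tip + s.shaft_length_mm * self.axis
        # orthonormal frame perpendicular to the lead axis
        u = np.cross(self.axis, [0.0, 0.0, 1.0])
        u = np.cross(self.axis, [0.0, 1.0, 0.0]) if np.linalg.norm(u) < 1e-6 else u
        self.u = u / np.linalg.norm(u)
        self.v = np.cross(self.axis, self.u)
        self.level_center = self.tip + s.contact_level_offset_mm * self.axis
        half = 0.5 * s.contact_length_mm
        self.contacts = []
        for k in range(s.contacts_per_level):
            ang = 2.0 * np.pi * k / s.contacts_per_level
            c = (self.level_center
                 + s.contact_ring_radius_mm * (np.cos(ang) * self.u + np.sin(ang) * self.v))
            self.contacts.append((c - half * self.axis, c + half * self.axis))

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        """Scene intensity at physical points (..., 3), CT units."""
        p = pts.reshape(-1, 3)
        val = np.full(len(p), AIR)
        r_out = np.linalg.norm(p / self.outer, axis=-1)
        m = _smooth_in((r_out - 1.0) * self.outer.min())
        val = val * (1 - m) + SKULL * m
        r_in = np.linalg.norm(p / self.inner, axis=-1)
        m = _smooth_in((r_in - 1.0) * self.inner.min())
        val = val * (1 - m) + BRAIN * m
        m = _smooth_in(_segment_distance(p, self.tip, self.shaft_end) - self.spec.shaft_radius_mm)
        val = val * (1 - m) + SHAFT * m
        for a, b in self.contacts:
            m = _smooth_in(_segment_distance(p, a, b) - self.spec.contact_radius_mm)
            val = val * (1 - m) + CONTACT * m
        return val.reshape(pts.shape[:-1])

    def init_landmarks(self) -> np.ndarray:
        """Three non-collinear skull/anatomy loci for initialization."""
        return np.array([[14.0, 2.0, 6.0], [-10.0, 12.0, -4.0], [-2.0, -13.0, 10.0]])

    def eval_landmarks(self) -> np.ndarray:
        """Five held-out targets: electrode tip, the 3 contact centers, and
        a deep anatomical locus."""
        centers = [0.5 * (a + b) for a, b in self.contacts]
        return np.array([self.tip, *centers, [8.0, 9.0, -7.0]])


def intensity_remap(v: np.ndarray, kind: str = "gamma") -> np.ndarray:
    """Monotone nonlinear CT-units -> FDCT-units map emulating multimodality."""
    if kind == "identity":
        return np.asarray(v, dtype=float)
    return _REMAP_SCALE * np.power(np.clip(v, 0.0, None) / CONTACT, _REMAP_GAMMA)


def intensity_remap_inverse(v: np.ndarray, kind: str = "gamma") -> np.ndarray:
    if kind == "identity":
        return np.asarray(v, dtype=float)
    return CONTACT * np.power(np.clip(v, 0.0, None) / _REMAP_SCALE, 1.0 / _REMAP_GAMMA)


# ---------------------------------------------------------------------------
# transforms and grids
# ---------------------------------------------------------------------------

def sample_transform(rot_ranges_deg, trans_ranges_mm, seed_or_rng,
                     center=(0.0, 0.0, 0.0)) -> RigidTransform3D:
    """Uniform rigid draw within +-range per axis, centered at ``center``."""
    rot = np.asarray(rot_ranges_deg, dtype=float)
    tra = np.asarray(trans_ranges_mm, dtype=float)
    if np.any(rot < 0) or np.any(tra < 0):
        raise PhantomSpecError("transform ranges must be non-negative")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    angles = np.deg2rad(rng.uniform(-rot, rot))
    shifts = rng.uniform(-tra, tra)
    return params_to_transform(np.concatenate([angles, shifts]), center)


def _centered_grid(size, spacing, center) -> tuple[np.ndarray, np.ndarray]:
    """(origin, n) for an axis-aligned grid whose physical center is ``center``."""
    size = np.asarray(size)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(center, dtype=float) - (size - 1) / 2.0 * spacing
    return origin, size


def _grid_points(vol: Volume3D, z0: int, z1: int) -> np.ndarray:
    nx, ny, _ = vol.size
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(z0, z1), indexing="ij")
    return index_to_physical(vol, np.stack([ix, iy, iz], axis=-1))


def _check_fov_containment(spec: PhantomSpec, T_true: RigidTransform3D,
                           fdct_center: np.ndarray) -> None:
    """The FDCT cylinder, mapped back to CT space, must sit inside the CT FOV."""
    r = 0.5 * min(spec.fdct_size[0] * spec.fdct_spacing_mm[0],
                  spec.fdct_size[1] * spec.fdct_spacing_mm[1])
    h = 0.5 * spec.fdct_size[2] * spec.fdct_spacing_mm[2]
    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    rim = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros_like(ang)], axis=-1)
    boundary = np.concatenate([rim + [0, 0, -h], rim, rim + [0, 0, h]])
    in_ct = apply(invert(T_true), boundary + fdct_center)
    half = np.asarray(spec.ct_size) * np.asarray(spec.ct_spacing_mm) / 2.0
    if np.any(np.abs(in_ct) > half):
        raise PhantomSpecError(
            "FDCT field of view is not contained in the CT field of view "
            "under the drawn transform; enlarge the CT grid or shrink the FDCT grid")


def _rasterize(scene, vol: Volume3D, to_scene=None, chunk: int = 32) -> None:
    for z0 in range(0, vol.size[2], chunk):
        z1 = min(z0 + chunk, vol.size[2])
        pts = _grid_points(vol, z0, z1)
        if to_scene is not None:
            pts = apply(to_scene, pts)
        vol.data[:, :, z0:z1] = scene(pts)


def make_phantom(spec: PhantomSpec | None = None, seed: int | None = None) -> PhantomBundle:
    """Generate a phantom bundle; all randomness derives from ``seed``
    (falling back to ``spec.seed``)."""
    spec = PhantomSpec() if spec is None else spec
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    scene = _Scene(spec)

    # CT grid centered on the scene; the true transform rotates about it
    T_true = sample_transform(spec.max_rotation_deg, spec.max_translation_mm, rng,
                              center=(0.0, 0.0, 0.0))
    # FDCT grid centered on the electrode region as a narrow-FOV scanner would be
    fdct_center = apply(T_true, np.zeros(3))
    _check_fov_containment(spec, T_true, fdct_center)

    ct_origin, _ = _centered_grid(spec.ct_size, spec.ct_spacing_mm, np.zeros(3))
    ct = Volume3D(np.zeros(spec.ct_size), spec.ct_spacing_mm, ct_origin)
    _rasterize(scene, ct)

    fdct_origin, _ = _centered_grid(spec.fdct_size, spec.fdct_spacing_mm, fdct_center)
    fdct = Volume3D(np.zeros(spec.fdct_size), spec.fdct_spacing_mm, fdct_origin)
    _rasterize(scene, fdct, to_scene=invert(T_true))
    fdct.data[...] = intensity_remap(fdct.data, spec.intensity_remap)

    # cylindrical FOV cut-out in the FDCT grid
    nx, ny, nz = fdct.size
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rad = np.hypot((ix - cx) * fdct.spacing[0], (iy - cy) * fdct.spacing[1])
    r_fov = 0.5 * min(nx * fdct.spacing[0], ny * fdct.spacing[1])
    mask = (rad <= r_fov)[:, :, None]

    ct.data += rng.normal(0.0, spec.ct_noise_sd, ct.size) if spec.ct_noise_sd > 0 else 0.0
    noise = rng.normal(0.0, spec.fdct_noise_sd, fdct.size) if spec.fdct_noise_sd > 0 else 0.0
    fdct.data[...] = np.where(mask, fdct.data + noise, 0.0)
    ct.data = np.round(ct.data).astype(np.int16)
    fdct.data = np.round(np.clip(fdct.data, -32768, 32767)).astype(np.int16)

    init_f = scene.init_landmarks()
    eval_f = scene.eval_landmarks()
    init_m = apply(T_true, init_f)
    if spec.landmark_noise_sd_mm > 0:
        init_m = init_m + rng.normal(0.0, spec.landmark_noise_sd_mm, init_m.shape)
    eval_m = apply(T_true, eval_f)

    sep = np.linalg.norm(init_f[:, None, :] - eval_f[None, :, :], axis=-1)
    if np.any(sep < 1e-6):
        raise PhantomSpecError("initialization and evaluation landmarks overlap")

    return PhantomBundle(
        ct=ct, fdct=fdct, true_transform=T_true,
        init_pairs=LandmarkPairSet(init_f, init_m, ["init1", "init2", "init3"]),
        eval_pairs=LandmarkPairSet(
            eval_f, eval_m, ["tip", "contact1", "contact2", "contact3", "deep"]))


def write_bundle(bundle: PhantomBundle, out_dir) -> dict[str, str]:
    """Write the bundle file set; returns {role: path}."""
    from .io import write_mha, write_points, write_transform

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct": out / "ct.mha",
        "fdct": out / "fdct.mha",
        "true_transform": out / "true_transform.txt",
        "init_points_fixed": out / "init_points_fixed.txt",
        "init_points_moving": out / "init_points_moving.txt",
        "eval_points_fixed": out / "eval_points_fixed.txt",
        "eval_points_moving": out / "eval_points_moving.txt",
    }
    write_mha(bundle.ct, paths["ct"])
    write_mha(bundle.fdct, paths["fdct"])
    write_transform(bundle.true_transform, paths["true_transform"])
    write_points(bundle.init_pairs.fixed_points, paths["init_points_fixed"], "CT-space init landmarks")
    write_points(bundle.init_pairs.moving_points, paths["init_points_moving"], "FDCT-space init landmarks")
    write_points(bundle.eval_pairs.fixed_points, paths["eval_points_fixed"], "CT-space eval points")
    write_points(bundle.eval_pairs.moving_points, paths["eval_points_moving"], "FDCT-space eval points")
    return {k: str(v) for k, v in paths.items()}
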