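import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fdctreg import PhantomSpec, RigidTransform3D, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_geometry(rng, size=(5, 6, 7)):
    """A random but valid volume geometry."""
    direction = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31)))).as_matrix()
    spacing = rng.uniform(0.1, 3.0, 3)
    origin = rng.uniform(-100, 100, 3)
    return Volume3D(rng.normal(size=size), spacing, origin, direction)


def random_rigid(rng, max_angle=np.pi, max_shift=50.0, center=None):
    R = Rotation.from_euler("ZYX", rng.uniform(-max_angle, max_angle, 3)).as_matrix()
    t = rng.uniform(-max_shift, max_shift, 3)
    c = rng.uniform(-20, 20, 3) if center is None else np.asarray(center, dtype=float)
    return RigidTransform3D(R, t, c)


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Coarse desk-scale phantom: same physical FOVs as the default spec at
    half resolution — fast enough for per-test registration runs."""
    kw = dict(ct_size=(48, 48, 24), ct_spacing_mm=(2.0, 2.0, 3.5),
              fdct_size=(64, 64, 64), fdct_spacing_mm=(0.7, 0.7, 0.7))
    kw.update(overrides)
    return PhantomSpec(**kw)
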