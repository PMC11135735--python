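import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from softarm import SyntheticArmSpec, TrajectorySet


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_rigid(rng):
    """Factory for random rotation + translation pairs."""

    def make():
        q = Rotation.random(rng=rng)
        t = rng.uniform(-100, 100, size=3)
        return q, t

    return make


def random_triple(rng, scale=100.0, min_area=1e-3):
    """A random non-degenerate 3-point triple (rejection sampled)."""
    while True:
        pts = rng.uniform(-scale, scale, size=(3, 3))
        v1 = pts[1] - pts[0]
        v2 = pts[2] - pts[0]
        if np.linalg.norm(np.cross(v1, v2)) > min_area:
            return pts


@pytest.fixture
def small_traj(rng):
    """10-frame, 5-marker trajectory with mild random motion, no gaps."""
    base = np.array(
        [[0.0, 0, 0], [20, 5, 0], [40, 8, 3], [60, 5, 6], [80, 0, 10]]
    )
    positions = base[None] + rng.normal(0, 0.5, size=(10, 5, 3))
    return TrajectorySet(
        marker_labels=[f"m{i}" for i in range(1, 6)],
        positions=positions,
        sample_rate=150.0,
    )


@pytest.fixture
def arc_spec():
    return SyntheticArmSpec(arc_radius=50.0, marker_spacing=20.0, n_frames=5)
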