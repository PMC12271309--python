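import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bodycomp import CorruptionSpec, PhantomSpec, corrupt_segmentation, make_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """A small-but-complete phantom: all six classes, 3 slices."""
    return PhantomSpec(n_slices=3, in_plane=(96, 72))


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return make_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def corrupted_raters(small_phantom):
    """Five imperfect raters at increasing corruption, deterministic seeds."""
    return [
        corrupt_segmentation(
            small_phantom, CorruptionSpec(displacement_mm=0.5 + 0.7 * j, seed=100 + j)
        )
        for j in range(5)
    ]


def random_mask_pair(seed: int, shape=(8, 9, 10)):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < 0.4, rng.random(shape) < 0.4
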