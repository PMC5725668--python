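import numpy as np
import pytest

from carti3d import PipelineConfig
from carti3d.phantom import small_spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def flat_spec():
    """Noise-free flat-plateau phantom: exact analytic ground truth."""
    return small_spec(
        noise_sd=0.0,
        dome_height=0.0,
        thickness_ramp=0.0,
        cartilage_thickness_medial=50.0,
        cartilage_thickness_lateral=50.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Scaled-down default phantom used for fast end-to-end tests."""
    return small_spec(seed=0)


@pytest.fixture(scope="session")
def small_config(small_phantom_spec):
    return PipelineConfig(voi=small_phantom_spec.voi)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
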