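import numpy as np
import pytest

from hepavol.phantom import PhantomConfig, make_phantom
from hepavol.pipeline import RunConfig, train_on_phantom

#: easy-contrast phantom regime used for pipeline-level checks: lesions large
#: relative to the 11-voxel texture window, clear tumor/parenchyma contrast
EASY_PHANTOM = dict(
    shape=(48, 64, 64),
    liver_semiaxes_mm=(30.0, 40.0, 44.0),
    tumor_count=4,
    tumor_radius_range_mm=(8.0, 12.0),
    tumor_hu_mean=60.0,
    tumor_hu_sigma=0.0,
    noise_sigma=8.0,
    tumor_volume_scales=1.5,
    tumor_hu_shifts=-10.0,
)


@pytest.fixture(scope="session")
def easy_phantom_block():
    return dict(EASY_PHANTOM)


@pytest.fixture(scope="session")
def easy_phantom_pair():
    """One rendered pre/post pair with ground truth (seed 42)."""
    return make_phantom(PhantomConfig(**EASY_PHANTOM, seed=42))


@pytest.fixture(scope="session")
def trained_model(easy_phantom_block):
    """Voxel classifier trained on a phantom disjoint from all test pairs."""
    cfg = RunConfig(phantom=easy_phantom_block, seed=11)
    return train_on_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
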