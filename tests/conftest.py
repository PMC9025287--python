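import numpy as np
import pytest

from habitatpipe import cohort as co


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small image-mode cohort spec for fast end-to-end style tests."""
    return co.development_spec(
        n_patients=4,
        volume_shape=(28, 28, 10),
        voxel_spacing=(1.2, 1.2, 2.0),
        tumor_radius_range=(5.0, 8.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def table2_sample():
    """A 60k-voxel PFV sample at the reference habitat mixture."""
    pfvs, labels = co.sample_pfvs(60_000, seed=42)
    return pfvs, labels
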