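import numpy as np
import pytest

from cariesseg.experiments import scaled_selftrain_study
from cariesseg.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_synthetic_dataset():
    """20 full-size (300x300) synthetic pairs under the default conditions."""
    return generate_dataset(20, SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick-to-train dataset: 40 images of 64x64 with ~6 px lesions."""
    config = SyntheticConfig(
        height=64, width=64, n_teeth=2, lesion_side_mean=6.0, lesion_side_sd=1.0
    )
    return generate_dataset(40, config, seed=11)


@pytest.fixture(scope="session")
def selftrain_study():
    """The reduced-scale three-arm study (3 seeds); shared across tests.

    This is the expensive fixture of the suite (a few minutes on one CPU);
    every test that needs end-to-end results reads from it.
    """
    return scaled_selftrain_study(seed=0, n_seeds=3)
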