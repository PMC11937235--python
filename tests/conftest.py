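import numpy as np
import pytest

from twinpaths.sem_core import BiometricCov
from twinpaths.synthetic_data import SimConfig, simulate_twins


def ae_config(seed, n_mz=1500, n_dz=1500, a=0.54, e=0.46, trait="y"):
    """Univariate AE generative config on pooled MZ/DZ groups."""
    return SimConfig(
        seed=seed,
        traits=[trait],
        group_pair_counts={"MZ": (n_mz, 0), "DZ": (n_dz, 0)},
        generative=(BiometricCov(1, ("A", "E")), {"A_1_1": a, "E_1_1": e}),
    )


@pytest.fixture(scope="session")
def ae_dataset():
    """Moderate AE cohort (h2 = 0.54) reused by fitting tests."""
    return simulate_twins(ae_config(seed=101))


@pytest.fixture(scope="session")
def small_ae_dataset():
    return simulate_twins(ae_config(seed=202, n_mz=60, n_dz=60))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
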