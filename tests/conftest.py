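import numpy as np
import pytest

from snpmix.simulate import ArrayDesign, NoiseSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_design() -> ArrayDesign:
    """A reduced design that keeps simulation-backed tests fast."""
    return ArrayDesign(I=2, J=2, K=4, L=3, m=40, inconsistent_fraction=0.5)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_dataset(small_design, NoiseSpec(), seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
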