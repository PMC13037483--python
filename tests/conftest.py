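import numpy as np
import pytest
from hypothesis import settings

from qsrr import DescriptorTable, SyntheticSpec, generate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    """10 x 4 random table with a linear response."""
    X = rng.normal(size=(10, 4))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 1.5
    return DescriptorTable(
        compound_ids=[f"c{i}" for i in range(10)],
        descriptor_names=["d1", "d2", "d3", "d4"],
        values=X,
        response=y,
    )


@pytest.fixture
def linear_dataset():
    """Default-shape synthetic dataset with a noiseless linear surface."""
    return generate(SyntheticSpec(n=75, K=40, k_true=4, noise_sd=0.0, seed=11))


@pytest.fixture
def nonlinear_dataset():
    return generate(
        SyntheticSpec(n=75, K=30, k_true=3, surface="nonlinear", noise_sd=0.02, seed=7)
    )
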