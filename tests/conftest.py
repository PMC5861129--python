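import pytest

from hopflow import (
    GroundTruth,
    NoiseModel,
    default_ground_truth,
    generate_dataset,
    initial_designs,
)


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return default_ground_truth()


@pytest.fixture(scope="session")
def noiseless_dataset(truth):
    """18 strains spanning the promoter space, no measurement noise."""
    designs = initial_designs(truth.catalog, n=18, seed=1)
    return generate_dataset(designs, truth, NoiseModel.noiseless(), replicates=3, seed=1)


@pytest.fixture(scope="session")
def noisy_dataset(truth):
    """18 strains with the default replicate noise (protein CV 0.2, titer CV 0.15)."""
    designs = initial_designs(truth.catalog, n=18, seed=2)
    return generate_dataset(designs, truth, NoiseModel(), replicates=3, seed=2)
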