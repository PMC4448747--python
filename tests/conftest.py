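import pytest

from promtime import GeneratorConfig, generate, worked_example_fixture


@pytest.fixture
def worked_example():
    return worked_example_fixture()


@pytest.fixture
def small_dataset():
    dataset, truth = generate(GeneratorConfig(n_compounds=30, seed=11))
    return dataset, truth


def random_dataset(seed, n_compounds=8):
    """Small random synthetic dataset for property checks (<=100 records)."""
    config = GeneratorConfig(
        n_compounds=n_compounds,
        seed=seed,
        promiscuity_distribution={1: 0.7, 2: 0.15, 3: 0.1, 7: 0.04, 25: 0.01},
        debut_multiplicity=0.2,
    )
    dataset, _ = generate(config)
    return dataset
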