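import pytest

from msynnet.simulate import mammal_scenario, plant_scenario, simulate_dataset


@pytest.fixture(scope="session")
def mammal_sim():
    """One shared run of the mammal scenario (duplication + RNA
    transposition on an ingroup stem)."""
    return simulate_dataset(mammal_scenario(seed=11))


@pytest.fixture(scope="session")
def plant_sim():
    """One shared run of the plant scenario (root WGT + fractionation,
    lineage-specific transposition)."""
    return simulate_dataset(plant_scenario(seed=11))
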