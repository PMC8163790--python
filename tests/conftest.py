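import pytest

from proteotype.pipeline import run_simulated
from proteotype.simulate import SimulationDesign, TruthConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        n_strains=4,
        mice_per_strain_per_sex=3,
        n_controls_per_sex=6,
        n_plates=3,
        pooled_refs_per_plate=9,
        n_proteins=40,
    )


@pytest.fixture(scope="session")
def small_truth_config():
    return TruthConfig(n_sex_effects=4, n_secondary_ko_effects=2)


@pytest.fixture(scope="session")
def small_dataset(small_design, small_truth_config):
    return simulate_dataset(small_design, small_truth_config, seed=7)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    return run_simulated(small_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-shaped dataset: 218 study samples x 226 proteins."""
    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def default_run(default_dataset):
    return run_simulated(default_dataset)
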