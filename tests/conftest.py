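import pytest

from srnapipe import pipeline
from srnapipe.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim_data():
    """Default-condition simulated dataset (seed 1)."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def run_result(sim_data):
    """Full pipeline result on the default simulated dataset."""
    return pipeline.run_from_data(sim_data)


@pytest.fixture(scope="session")
def noise_free_data():
    """Small noise-free, contaminant-free dataset: tier assignment should
    match ground truth exactly."""
    cfg = SimulationConfig(seed=5, depth_per_library=20_000,
                           substitution_rate=0.0, contaminant_fraction=0.0,
                           low_quality_fraction=0.0)
    return simulate_all(cfg)
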