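import pytest

from rasprok.pipeline import PipelineOptions, run_census_pipeline
from rasprok.synthetic_data import SimulationConfig, generate_census


@pytest.fixture(scope="session")
def default_census():
    """The default study conditions: 30 genomes, ~6 planted items each."""
    return generate_census(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_census):
    """Full pipeline run on the default census (shared across tests)."""
    return run_census_pipeline(default_census, PipelineOptions(seed=1))


@pytest.fixture(scope="session")
def small_census():
    """A reduced census for tests that re-run harvesting repeatedly."""
    return generate_census(
        SimulationConfig(
            seed=5,
            n_genomes=8,
            genes_per_replicon=48,
            mgla_systems=(3, 2, 2, 2, 2),
            rup_systems=(2, 2),
            n_decoy_abc=2,
            n_truncations=2,
            n_roco=2,
        )
    )
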