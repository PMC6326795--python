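import pytest

from progem import (
    PipelineConfig,
    SimulationConfig,
    run_pipeline,
    simulate_dataset,
    table2_fixtures,
)


def run_dataset(ds, config=PipelineConfig()):
    """Run the pipeline over an in-memory dataset bundle."""
    return run_pipeline(
        ds.sentinels,
        ds.genes,
        ds.proxies,
        ds.eqtls,
        ds.consequences,
        ds.annotation_sets,
        config,
    )


@pytest.fixture(scope="session")
def worked_example():
    return table2_fixtures()


@pytest.fixture(scope="session")
def worked_reports(worked_example):
    return {r.sentinel.rsid: r for r in run_dataset(worked_example)}


@pytest.fixture(scope="session")
def sim_dataset():
    return simulate_dataset(SimulationConfig(n_loci=50, seed=11))


@pytest.fixture(scope="session")
def sim_reports(sim_dataset):
    return run_dataset(sim_dataset)
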