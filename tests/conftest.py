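import pytest

from melcensus.core_io import PipelineConfig
from melcensus.pipeline import run_pipeline
from melcensus.simulate import mini_params, benchmark_params, simulate_dataset


@pytest.fixture(scope="session")
def benchmark_sim():
    """The benchmark dataset: 12 species, 6 families, TWGD clade, seed 42."""
    return simulate_dataset(benchmark_params(42))


@pytest.fixture(scope="session")
def benchmark_run_fixture(benchmark_sim):
    """Full pipeline run over the benchmark dataset (100 bootstrap reps)."""
    cfg = PipelineConfig(rng_seed=42, bootstrap_reps=100)
    return run_pipeline(
        cfg, benchmark_sim.genomes, benchmark_sim.refs, benchmark_sim.species_meta
    )


@pytest.fixture(scope="session")
def mini_sim():
    """Small 4-species dataset for fast structural checks."""
    return simulate_dataset(mini_params(7))
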