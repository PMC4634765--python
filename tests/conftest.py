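import pytest

import primarytx as px
from primarytx.pipeline import analyze


@pytest.fixture(scope="session")
def default_sim():
    """The default planted scene (seed 42) with its 12 simulated libraries."""
    params = px.SimulationParams(seed=42)
    genome, truth = px.generate_genome(params)
    libs = px.simulate_libraries(genome, truth, params)
    return genome, truth, libs


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full pipeline output on the default scene, computed once per session."""
    genome, truth, libs = default_sim
    return analyze(genome, libs, operons=truth.predicted_operons)


@pytest.fixture(scope="session")
def default_tss(default_analysis):
    return default_analysis.tss
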