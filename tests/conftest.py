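import pytest

from srnamir import report, simulate


@pytest.fixture(scope="session")
def default_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def pipeline(default_config) -> report.PipelineResult:
    """One full pipeline run on the default synthetic study (shared)."""
    return report.run_all(default_config)


@pytest.fixture(scope="session")
def bundle(pipeline) -> simulate.ReferenceBundle:
    return pipeline.bundle


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    """A fast configuration for tests that rebuild the study themselves."""
    return simulate.SimulationConfig(
        n_transcripts=30,
        n_conserved_mirnas=5,
        n_novel_mirnas=6,
        depth_per_library=12_000,
        seed=7,
    )
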