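import pytest

from ceranet import PipelineConfig, SimulationConfig, run_all, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic five-sample dataset (seed 42)."""
    return simulate_all(SimulationConfig())


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic fixture (seed 42)."""
    outdir = tmp_path_factory.mktemp("run")
    report = run_all(PipelineConfig(), outdir)
    return report, outdir
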