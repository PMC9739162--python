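import numpy as np
import pytest

from circsponge.report import PipelineConfig, run_pipeline
from circsponge.synthetic import SimConfig, generate_study


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """The default study conditions with a fixed seed."""
    return SimConfig(seed=101)


@pytest.fixture(scope="session")
def bundle(sim_config, tmp_path_factory):
    """One synthetic study shared by the whole session."""
    return generate_study(sim_config, tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full end-to-end pipeline run on a simulated study."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=101, outdir=str(outdir), simulate=True)
    return run_pipeline(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2029)
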