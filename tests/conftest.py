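import numpy as np
import pytest

from eyevolve.config import PipelineConfig
from eyevolve.io import configure_logging
from eyevolve.pipeline import RunDirectory, run_pipeline
from eyevolve.simulate import SimulationConfig, generate_dataset

configure_logging(False)

#: compact study: same divergence/noise conditions as the defaults, fewer families
SMALL_SIM = dict(n_families=40, n_duplications=4, n_dual_origin_duplications=2,
                 n_selection_events=4, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One generated dataset shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("dataset")
    return generate_dataset(SimulationConfig(**SMALL_SIM), outdir)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run (simulation through scoring) shared by tests."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(seed=SMALL_SIM["seed"])
    report = run_pipeline(cfg, outdir, sim_config=SimulationConfig(**SMALL_SIM))
    return RunDirectory(outdir), report
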