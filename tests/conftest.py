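import numpy as np
import pytest

from larpclip import SimulationSpec, generate_transcriptome
from larpclip.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    return SimulationSpec(n_transcripts=40, mrnaseq_reads=20_000, seed=11)


@pytest.fixture(scope="session")
def small_data(small_spec):
    transcripts, truth = generate_transcriptome(small_spec)
    return transcripts, truth, small_spec


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline at the default study conditions (300 transcripts,
    20% RP, both conditions, seed 7)."""
    outdir = tmp_path_factory.mktemp("default_run")
    config = RunConfig(outdir=outdir, seed=7, condition="both")
    return run_pipeline(config), config


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
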