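import numpy as np
import pytest

from altprom.pipeline import PipelineParams, run_pipeline
from altprom.simulate import SimConfig, simulate_cohort

TEST_SEED = 11


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic cohort: 20 tumor / 20 adjacent / 4 normal samples,
    60 genes (10 annotated-alternative MP, 10 novel-alternative MP),
    10 eRNA pairs, 10 exonic recapping artifacts, 5 small RNAs."""
    return simulate_cohort(SimConfig(seed=TEST_SEED))


@pytest.fixture(scope="session")
def pipeline_result(sim_default):
    return run_pipeline(sim_default, PipelineParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)


@pytest.fixture()
def toy_genome():
    # chr1: fixed 60-base sequence for initiator / G-correction tests
    return {"chr1": "AACATGCGTACCAGGTTCACGTGACCGATCCAGGCTTACGGATCCGTAGCCATGGCATAA"}
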