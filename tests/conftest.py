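import numpy as np
import pytest

from netbeh import synth
from netbeh.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def small_synth_config():
    """Reduced cohort for unit tests: fewer subjects and frames."""
    return synth.SyntheticConfig(
        n_patients=8,
        n_observations=10,
        n_controls=7,
        n_volumes=80,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_synth_config):
    return synth.generate_cohort(small_synth_config)


@pytest.fixture(scope="session")
def fast_pipeline_config(small_synth_config):
    return PipelineConfig(
        synthetic=small_synth_config,
        alphasim_iterations=100,
        run_structural=False,
        rng_seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
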