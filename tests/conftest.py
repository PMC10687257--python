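import numpy as np
import pytest

from neuroscreen.data_model import PipelineConfig
from neuroscreen.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    return PipelineConfig.tiny(seed=0, epochs=3)


@pytest.fixture(scope="session")
def small_cohort():
    """24 subjects with the default planted effects; shared across tests."""
    spec = CohortSpec.tiny(24)
    return generate_cohort(spec, np.random.default_rng(42))
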