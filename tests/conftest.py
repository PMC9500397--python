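import numpy as np
import pytest
from hypothesis import settings

from vesselseg import PipelineConfig, SyntheticSpec, generate_synthetic_fundus
from vesselseg.pipeline import build_filters

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def synthetic_config():
    return PipelineConfig.from_preset("synthetic")


@pytest.fixture(scope="session")
def configured_filters(synthetic_config):
    """Symmetric + asymmetric filters configured once per session."""
    return build_filters(synthetic_config)


@pytest.fixture(scope="session")
def fundus_fixture():
    """One synthetic fundus image with exact gold and FOV masks."""
    return generate_synthetic_fundus(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def fundus_batch():
    """The frozen ten-image synthetic evaluation set (seeds 1..10)."""
    return [generate_synthetic_fundus(SyntheticSpec(seed=s)) for s in range(1, 11)]
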