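import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import methbatch as mb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """The desk-scale reference study: 8 slides x 12 arrays, 2,000 probes."""
    return mb.generate_study(mb.StudyConfig(seed=1))


@pytest.fixture(scope="session")
def default_run():
    """Full diagnostic pipeline on the reference study (EB correction,
    gender and cell fraction declared, genotype structure undeclared)."""
    return mb.run_pipeline(mb.PipelineConfig(study=mb.StudyConfig(seed=1), seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
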