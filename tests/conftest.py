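import numpy as np
import pytest

from ehrcollab import datasets, pipeline, simulate


@pytest.fixture(scope="session")
def example_events():
    return datasets.example_audit_events()


@pytest.fixture(scope="session")
def survey_scores():
    return datasets.example_survey_scores()


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic run shared across tests."""
    return simulate.generate(simulate.SimConfig(seed=11))


@pytest.fixture(scope="session")
def pipe_default(sim_default):
    return pipeline.run(sim_default.events, hcw_meta=sim_default.hcw_meta)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
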