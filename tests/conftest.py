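import logging

import pytest

from merip_conjoint import SimulationConfig, simulate_study

logging.getLogger("merip_conjoint").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def demo_study():
    """A small complete synthetic study shared across test modules."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def demo_models(demo_study):
    return demo_study.models
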