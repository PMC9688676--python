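import numpy as np
import pytest

from quenchfit import FitConfig, default_scenarios
from quenchfit.synthetic import noiseless_timecourse


@pytest.fixture(scope="session")
def scenarios():
    return {s.name: s for s in default_scenarios()}


@pytest.fixture(scope="session")
def clean_timecourses(scenarios):
    """Noiseless forward-model band fractions per scenario."""
    return {name: noiseless_timecourse(s) for name, s in scenarios.items()}


@pytest.fixture(scope="session")
def fast_config():
    """Reduced optimizer effort for unit tests; noiseless fits converge via
    the least-squares polish, so a small GA stage suffices."""
    return FitConfig(ga_population=32, ga_generations=40, n_polish=4, seed=7)


@pytest.fixture
def times20():
    return np.geomspace(0.005, 10, 20)

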