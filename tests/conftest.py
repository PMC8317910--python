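import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from pehsurv.simulate import SimulationConfig, generate_population
from pehsurv.studies import study_config
from pehsurv import recode


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small population with programmed PEH effects (1.6, 1.2, 1.4)."""
    return study_config(123, n_women=800, log_hr_peh=(np.log(1.6), np.log(1.2), np.log(1.4)))


@pytest.fixture(scope="session")
def small_population(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_observations(small_config, small_population):
    women, children = small_population
    return recode.build_survival_data(women, children, small_config.interview_cmc)


@pytest.fixture()
def toy_observations() -> pd.DataFrame:
    """Hand-sized survival frame: two groups, known death counts (3/10, 1/10)."""
    rows = []
    for i in range(10):
        rows.append({"child_id": i, "time_months": 10.0 + i, "event": i < 3,
                     "weight": 2.0, "g": "a"})
    for i in range(10):
        rows.append({"child_id": 10 + i, "time_months": 12.0 + i, "event": i < 1,
                     "weight": 2.0, "g": "b"})
    return pd.DataFrame(rows)
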