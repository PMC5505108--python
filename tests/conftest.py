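import numpy as np
import pandas as pd
import pytest

import ruraldce as rd
from ruraldce import config as cfgmod


@pytest.fixture(scope="session")
def base_config():
    return cfgmod.load_config()


@pytest.fixture(scope="session")
def survey_space(base_config):
    """The six-attribute job-posting space of the study instrument."""
    return cfgmod.attribute_space(base_config)


@pytest.fixture(scope="session")
def printed_params(base_config):
    """Published coefficient table as an estimation result object."""
    return cfgmod.parameter_table(base_config)


@pytest.fixture(scope="session")
def survey_dgp(base_config, survey_space):
    return cfgmod.dgp_from_parameters(base_config, survey_space)


@pytest.fixture(scope="session")
def survey_design(survey_space):
    return rd.generate_design(survey_space, n_tasks=12, n_alternatives=2,
                              seed=11, n_candidates=100)


@pytest.fixture(scope="session")
def packages(base_config):
    return cfgmod.packages_from_config(base_config)


@pytest.fixture
def toy_space():
    """Two binary attributes; 2 coded columns."""
    return rd.build_attribute_space(
        {
            "attributes": [
                {"name": "a", "levels": ["lo", "hi"]},
                {"name": "b", "levels": ["lo", "hi"]},
            ]
        }
    )


def make_trajectory(recruits, start_year=2011):
    """Minimal trajectory carrying only new rural recruits per year."""
    years = [start_year + k for k in range(len(recruits) + 1)]
    df = pd.DataFrame(
        {"year": years, "new_public_rural": [0.0] + list(recruits)}
    )
    return rd.WorkforceTrajectory(df=df, rr=np.nan)


@pytest.fixture
def trajectory_factory():
    return make_trajectory
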