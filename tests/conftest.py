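import numpy as np
import pytest

from oxidiet import default_config, tables


@pytest.fixture(scope="session")
def printed():
    return tables.printed()


@pytest.fixture(scope="session")
def group_profiles():
    """Printed group-mean fatty-acid profiles per diet group."""
    return {g: tables.group_mean_profile(g) for g in tables.GROUPS}


@pytest.fixture(scope="session")
def study_config():
    """The default (study-condition) cohort configuration."""
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20180926)
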