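import logging

import numpy as np
import pytest

from bbsurvey.containers import RegionParams
from bbsurvey.synthdata import correlation_scenario, scenario_library

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def ibb_2014():
    return scenario_library()["ibb_2014"]


@pytest.fixture(scope="session")
def five_group_ibb(ibb_2014):
    """Ibb 2014 marginals for a 5-group subset with exchangeable(0.5) Omega."""
    names = ["potatoes", "rice", "vegetables", "pulses", "dairy"]
    idx = [ibb_2014.group_names.index(g) for g in names]
    return RegionParams(
        group_names=names,
        p=ibb_2014.p[idx],
        theta=ibb_2014.theta[idx],
        sigma=ibb_2014.sigma[idx],
        Omega=correlation_scenario("exchangeable", names, r=0.5),
        region="ibb_2014_5grp",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
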