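import numpy as np
import pytest

import stemopt as so
from stemopt.config import default_config
from stemopt.geometry import DesignVector


@pytest.fixture(scope="session")
def mid_design() -> DesignVector:
    return DesignVector.mid()


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def intact_field(cfg):
    return so.pipeline.intact_solution(cfg)


@pytest.fixture(scope="session")
def implanted_result(mid_design, cfg):
    return so.pipeline.implanted_solution(mid_design, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
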