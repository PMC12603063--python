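import numpy as np
import pytest

from grouplearn.learning_models import LearningParams
from grouplearn.task_design import make_schedule


@pytest.fixture(scope="session")
def schedule96():
    return make_schedule(4, 24, 0.75, seed=1)


@pytest.fixture
def m3_params():
    return LearningParams(0.3, 0.2, 0.4, 0.1, beta=1.0, v0_ingroup=0.5, v0_outgroup=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
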