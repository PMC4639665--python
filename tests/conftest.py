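import logging

import numpy as np
import pytest

from lncea.ln_model import LifetimeEvaluator, ThreeYearEvaluator
from lncea.param_model import ParamSet, base_case
from lncea.synth_data import calibrate_dialysis_table, make_life_table

# the age-dependent lifetime model legitimately renormalizes relapse rows at
# older ages; keep the suite's output readable
logging.getLogger("lncea.ln_model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def params() -> ParamSet:
    return base_case()


@pytest.fixture(scope="session")
def three_year(params) -> ThreeYearEvaluator:
    return ThreeYearEvaluator(params)


@pytest.fixture(scope="session")
def life_table():
    return make_life_table()


@pytest.fixture(scope="session")
def dialysis_table():
    return calibrate_dialysis_table()


@pytest.fixture(scope="session")
def lifetime(params, life_table, dialysis_table) -> LifetimeEvaluator:
    return LifetimeEvaluator(params, life_table, dialysis_table)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130917)
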