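import numpy as np
import pytest

from previnc.data import (
    load_coalminers_lifetable,
    load_coalminers_prevalence,
    load_diabetes_prevalence,
)
from previnc.lifetable import gompertz_from_lifetable
from previnc.rates import GompertzRate, RateRatioCurve


@pytest.fixture(scope="session")
def coalminers():
    return load_coalminers_prevalence()


@pytest.fixture(scope="session")
def coalminers_lifetable():
    return load_coalminers_lifetable()


@pytest.fixture(scope="session")
def diabetes():
    return load_diabetes_prevalence()


@pytest.fixture(scope="session")
def mortality_general(coalminers_lifetable):
    return gompertz_from_lifetable(coalminers_lifetable, "general")


@pytest.fixture(scope="session")
def mortality_diseased(coalminers_lifetable):
    return gompertz_from_lifetable(coalminers_lifetable, "breathlessness")


@pytest.fixture(scope="session")
def diabetes_mortality():
    """General mortality of German women, log-linear in age."""
    return GompertzRate(-11.35, 0.1061)


@pytest.fixture(scope="session")
def diabetes_rate_ratio():
    return RateRatioCurve()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
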