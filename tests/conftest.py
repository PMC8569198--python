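import pytest

from racewayrsm.datasets import load_table1, raceway_design, raceway_factors
from racewayrsm.design import generate_ccf


@pytest.fixture(scope="session")
def factors():
    return raceway_factors()


@pytest.fixture(scope="session")
def ccf_design(factors):
    return generate_ccf(factors, n_center=3)


@pytest.fixture(scope="session")
def table1():
    return raceway_design()


@pytest.fixture(scope="session")
def fixtures():
    return load_table1()
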