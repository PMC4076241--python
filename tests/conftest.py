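import numpy as np
import pytest

import glyconet as gn


@pytest.fixture(scope="session")
def db():
    return gn.builtin_database()


@pytest.fixture(scope="session")
def case1():
    return gn.case1_inputs()


@pytest.fixture(scope="session")
def case2():
    return gn.case2_inputs()


@pytest.fixture(scope="session")
def case3():
    return gn.case3_inputs()


@pytest.fixture(scope="session")
def case1_master(case1, db):
    """The consolidated Case-1 connection-inference pathway."""
    return gn.connection_network(list(case1.glycans), list(case1.enzyme_names), db=db)


@pytest.fixture(scope="session")
def case3_master(case3, db):
    """The consolidated Case-3 connection-inference pathway (synthetic roster)."""
    return gn.connection_network(list(case3.glycans), list(case3.enzyme_names), db=db)


@pytest.fixture(scope="session")
def m5gn(case2):
    return case2.glycan("M5Gn")


@pytest.fixture
def rng():
    return np.random.default_rng(20140630)
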