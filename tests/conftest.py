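import numpy as np
import pytest

from oligoband import fixtures


@pytest.fixture(scope="session")
def pig_genome():
    return fixtures.pig_genome()


@pytest.fixture(scope="session")
def demo_scheme():
    return fixtures.demo_scheme()


@pytest.fixture(scope="session")
def demo_panels(demo_scheme):
    # demo_scheme() colours the panel probes as a side effect
    return fixtures.demo_panels()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
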