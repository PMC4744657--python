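import numpy as np
import pytest

import hofaudit as ha


@pytest.fixture(scope="session")
def surrogate():
    return ha.SurrogateForceField()


@pytest.fixture(scope="session")
def probe_backend():
    """Surrogate with the canonical test probe: sigma(C)=2.0, eps=0.1."""
    return ha.SurrogateForceField(ha.SurrogateParams(sigma_overrides={"C": 2.0}))


@pytest.fixture(scope="session")
def helix10():
    return ha.make_polyalanine(10, "helix")


@pytest.fixture(scope="session")
def extended10():
    return ha.make_polyalanine(10, "extended")


@pytest.fixture(scope="session")
def clash_fixture():
    return ha.make_clash_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20150606)
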