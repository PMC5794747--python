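import pytest

from navclamp import gating_model as gm


@pytest.fixture(scope="session")
def wt():
    return gm.load_variant("WT", 22.0)


@pytest.fixture(scope="session")
def r1451c():
    return gm.load_variant("R1451C", 22.0)


@pytest.fixture(scope="session")
def r1451l():
    return gm.load_variant("R1451L", 22.0)


@pytest.fixture(scope="session")
def variants_22(wt, r1451c, r1451l):
    return {"WT": wt, "R1451C": r1451c, "R1451L": r1451l}


@pytest.fixture(scope="session")
def e_na():
    return gm.nernst_sodium(22.0)
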