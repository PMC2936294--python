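import numpy as np
import pytest

from pichia_mfa.ems import enumerate_ems
from pichia_mfa.model import load_pichia_model
from pichia_mfa.scenarios import load_scenarios


@pytest.fixture(scope="session")
def pichia():
    return load_pichia_model()


@pytest.fixture(scope="session")
def pichia_ems(pichia):
    return enumerate_ems(pichia)


@pytest.fixture(scope="session")
def scenarios():
    return load_scenarios()


@pytest.fixture(scope="session")
def scenario_by_id(scenarios):
    return {s.id: s for s in scenarios}


TOY_CHAIN = """
[metabolites]
Xin\texternal\t1
Xout\texternal\t1
A\tinternal\t1
B\tinternal\t1
[reactions]
r1\tXin -> A\tuptake
r2\tA -> B\tconversion
r3\tB -> Xout\tefflux
[exchange]
uptake\tr1\t1
efflux\tr3\t1
"""


@pytest.fixture()
def toy_chain():
    from pichia_mfa.model import loads_model

    return loads_model(TOY_CHAIN)
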