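import random

import pytest

from abnet.synthetic import sample_synthesis_instance as random_instance

__all__ = ["random_instance"]


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture(scope="session")
def pluripotency():
    from abnet.pluripotency import resetting_constraints, resetting_network
    return resetting_network(), resetting_constraints()


@pytest.fixture(scope="session")
def pluripotency_synthesis(pluripotency):
    from abnet.synthesis import synthesize
    net, cons = pluripotency
    return synthesize(net, cons, timeout=600)
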