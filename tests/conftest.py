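import numpy as np
import pytest

from stoopsim.morphology import (BirdMorphology, PhysicalConstants, FALCON,
                                 STARLING)


@pytest.fixture(scope="session")
def consts():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def falcon():
    return FALCON


@pytest.fixture(scope="session")
def starling():
    return STARLING


@pytest.fixture(scope="session")
def falcon_fixed():
    """Falcon with the fixed (tabulated) friction coefficient, for oracle
    comparisons that assume a span-independent drag coefficient."""
    return FALCON.with_options(friction_mode="fixed")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
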