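import numpy as np
import pytest

import splitkl as sk


@pytest.fixture(scope="session")
def double_well():
    return sk.make_system("double_well")


@pytest.fixture(scope="session")
def quartic():
    return sk.make_system("quartic")


@pytest.fixture(scope="session")
def dw_edges(double_well):
    """Shared 100-bin phase-space edges from a trial run at dt=0.6."""
    return sk.determine_edges(double_well, "OVRVO", 0.6, 10.0, rng_seed=7)
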