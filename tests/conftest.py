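import numpy as np
import pytest

from mepdsim import KNDyParams, MePDParams, update
from mepdsim.continuation import continue_equilibria, detect_codim1


@pytest.fixture(scope="session")
def mepd_defaults() -> MePDParams:
    return MePDParams()


@pytest.fixture(scope="session")
def kndy_defaults() -> KNDyParams:
    return KNDyParams()


@pytest.fixture(scope="session")
def kp_branch(mepd_defaults):
    """Equilibrium branch in Kp over [0, 3] at default parameters."""
    return continue_equilibria(mepd_defaults, "Kp", (0.0, 3.0))


@pytest.fixture(scope="session")
def hopf_point(kp_branch):
    hbs = [b for b in detect_codim1(kp_branch) if b.kind == "HB"]
    assert hbs, "expected a Hopf point on the default Kp branch"
    return hbs[0]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
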