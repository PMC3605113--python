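import numpy as np
import pytest

from prspower import PolygenicModel, StudyDesign, binary_trait


@pytest.fixture
def baseline_model():
    """Reduced-scale version of the two-trait baseline scenario."""
    return PolygenicModel(m=20000, vg1=0.4, vg2=0.3, rho12=0.65, pi0=0.95)


@pytest.fixture
def baseline_design():
    return StudyDesign(n1=2000, n2=2000, q0=0.0, q1=0.1)


@pytest.fixture
def cc_design():
    """Case/control design in the style of the large schizophrenia study."""
    t1 = binary_trait(0.01, P=3322 / 6909)
    t2 = binary_trait(0.01, P=2687 / 5343)
    return StudyDesign(n1=6909, n2=5343, trait1=t1, trait2=t2, q0=0.0, q1=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20130321)
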