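import numpy as np
import pytest

from dceident.signals import SampledSignal
from dceident.synthetic import TABLE_AA
from dceident.transport import ct_ltk
from dceident.vif import parker_vif_signal


@pytest.fixture(scope="session")
def vif():
    """Population VIF on the default 35-frame acquisition grid."""
    return parker_vif_signal()


@pytest.fixture(scope="session")
def aa_type1(vif):
    """Noise-free persistent-enhancement (Type I) tissue curve."""
    return ct_ltk(vif, TABLE_AA["I"])


@pytest.fixture
def constant_vif():
    """Constant plasma concentration: closed-form solutions exist."""
    t = np.linspace(0.0, 120.0, 25)
    return SampledSignal(t, np.full_like(t, 2.0), label="const")
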