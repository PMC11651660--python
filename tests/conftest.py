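import numpy as np
import pytest

from covashift.melt_model import StabilityParams
from covashift.competition_binding import CompetitionSetup


@pytest.fixture
def stability():
    """A typical ~30 kDa CA domain: Tm 60 C, dHu 500 kJ/mol, dCpu 17 kJ/(mol K)."""
    return StabilityParams(Tm_ref=333.15, dHu=500e3, dCpu=17e3)


@pytest.fixture
def cell_setup():
    """Cell-surface competition constants: Pt 5 nM, probe 10 nM at Kd 150 pM."""
    return CompetitionSetup(Pt=5e-9, Bt=10e-9, KdB=1.5e-10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
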