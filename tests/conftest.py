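import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None, deadline=None)
settings.load_profile("deterministic")

from fretbudget import SamplePopulation, TcspcModel, make_irf
from fretbudget.sefret_core import (
    FretSystem,
    IDEAL_SYSTEM,
    SYSTEM_CONFOCAL,
    SYSTEM_WIDEFIELD,
)


@pytest.fixture
def ideal_sys():
    return IDEAL_SYSTEM


@pytest.fixture
def confocal_sys():
    """Confocal CFP-YFP crosstalk/calibration (AER=0.60, DER=0.42, eta=0.52, eps=6.3)."""
    return SYSTEM_CONFOCAL


@pytest.fixture
def widefield_sys():
    return SYSTEM_WIDEFIELD


@pytest.fixture
def half_pop():
    """E=0.5 with half the donors interacting and all acceptors paired."""
    return SamplePopulation.from_fractions(0.5, 0.5, 1.0)


@pytest.fixture
def dirac_model():
    """High-end TCSPC reference: tau0=3 ns, 80 MHz, 256 bins, Dirac IRF."""
    return TcspcModel(tau0_ns=3.0, rep_rate_hz=80e6, n_bins=256, irf=make_irf("dirac"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
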