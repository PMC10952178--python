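import numpy as np
import pytest

from mhsd.params import ParameterSet
from mhsd.reporting import run_scenario
from mhsd.scenarios import baseline
from mhsd.sd_core import StockVector


class ToyParams:
    """Minimal params object for exercising the integrator on toy systems."""

    def __init__(self, names, values):
        self._init = StockVector(tuple(names), np.asarray(values, dtype=float), 0.0)

    def initial_stocks(self):
        return self._init.copy()


@pytest.fixture
def toy_params():
    return ToyParams


@pytest.fixture(scope="session")
def ref_params():
    return ParameterSet.reference()


@pytest.fixture(scope="session")
def baseline_traj(ref_params):
    """Baseline trajectory 2011-2029, shared across tests (deterministic)."""
    return run_scenario(ref_params, baseline(ref_params))
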