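import numpy as np
import pytest

from vbephys import protocols
from vbephys.model import ClampConfig, NeuronParams, preset, simulate_ladder
from vbephys.traces import make_step_protocol


@pytest.fixture(scope="session")
def passive_params():
    """Cell with every voltage-gated conductance removed."""
    return NeuronParams(
        Cm=67.0, g_leak=10.0, E_leak=-80.0,
        g_T=0.0, g_h=0.0, g_HVA=0.0, g_Na=0.0, g_K=0.0,
    )


@pytest.fixture(scope="session")
def quiet_cc():
    return ClampConfig.cc(seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def quiet_vc():
    return ClampConfig.vc(seed=0, noise_sd=0.0)


from helpers import hyp_ladder  # noqa: E402


@pytest.fixture(scope="session")
def nec_cc1000(quiet_cc):
    """Noise-free NEC response to the hyperpolarizing 1,000-ms ladder."""
    return simulate_ladder(preset("NEC"), hyp_ladder(), quiet_cc)


@pytest.fixture(scope="session")
def gaers_cc1000(quiet_cc):
    return simulate_ladder(preset("GAERS"), hyp_ladder(), quiet_cc)
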