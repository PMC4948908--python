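import numpy as np
import pytest

from vnboost import default_parameters


@pytest.fixture(scope="session")
def params():
    """Packaged default parameter set (gCa = 0.6 reference configuration)."""
    return default_parameters()


@pytest.fixture(scope="session")
def params_qif02(params):
    """QIF configuration at the reference calcium conductance 0.2."""
    return params.with_(gCa=0.2)


@pytest.fixture(scope="session")
def burst_spike_trains(params):
    """HH spike trains at the four printed example biases (shared, slow)."""
    from vnboost.hh import hh_spike_times

    return {
        mu: hh_spike_times(params, mu, 5000.0, dt=0.01)
        for mu in (18.0, 19.0, 22.0, 22.5)
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
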