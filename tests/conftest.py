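import numpy as np
import pytest

from corrdop import (AcquisitionParams, DopplerConfig, PhantomSpec,
                     simulate_rotational_scan, simulate_stationary_sequence)


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def rparams():
    return AcquisitionParams(scan_mode="rotational")


@pytest.fixture(scope="session")
def cfg():
    return DopplerConfig()


@pytest.fixture(scope="session")
def linear_scan(params):
    """Noisy stationary linear-tube scan reused across tests."""
    spec = PhantomSpec(kind="linear_tube", seed=7, flow_speed=3.15e-3,
                       snr_db=20.0, n_lines=201)
    return simulate_stationary_sequence(spec, params)


@pytest.fixture(scope="session")
def spiral_scan(rparams):
    """Full-revolution spiral scan (1000 lines) reused across tests."""
    spec = PhantomSpec(kind="spiral", seed=3, flow_speed=3e-3, snr_db=20.0)
    return simulate_rotational_scan(spec, rparams)


@pytest.fixture(scope="session")
def lumen_scan(rparams):
    """Constant-radius lumen scan with a superficial flow layer."""
    spec = PhantomSpec(kind="lumen", seed=5, flow_speed=0.0, snr_db=20.0,
                       n_lines=300, wobble_amp=0.0)
    return simulate_rotational_scan(spec, rparams)
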