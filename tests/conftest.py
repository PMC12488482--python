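import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from apcpulse import (
    KineticParameters,
    StimulusProtocol,
    SystemState,
    reference_simulate,
    simulate,
)


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def control_protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def control_traj(params, control_protocol):
    """Default stimulated run (S=3, PP onset 4 h) over 12 h."""
    return simulate(params, control_protocol, t_end=12.0, output_dt=0.05)


@pytest.fixture(scope="session")
def control_ref(params, control_protocol):
    """Fixed-step RK4 cross-check of the default run (dt coarse enough for
    unit tests; the full-resolution comparison lives in the acceptance
    suite)."""
    return reference_simulate(
        params, control_protocol, t_end=12.0, output_dt=0.05, dt=1e-3
    )


def series_close(a, b, tol):
    return float(np.max(np.abs(np.asarray(a) - np.asarray(b)))) <= tol
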