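import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wormtouch import CalciumTrace, ResponseModel, StimulusProtocol

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def model():
    return ResponseModel()


@pytest.fixture
def pulse_protocol():
    """One 40 psi / 1 s stimulus after a 10 s baseline, 30 s recording."""
    return StimulusProtocol.single_pulse(record_duration=30.0)


@pytest.fixture
def make_trace():
    """Build a normalized single-channel CalciumTrace from a dR/R0 array."""

    def _make(dRR, protocol=None, frame_interval=0.1, valid=None):
        dRR = np.asarray(dRR, dtype=float)
        n = dRR.size
        return CalciumTrace(
            time=np.arange(n) * frame_interval,
            I_G_roi=dRR,
            I_G_back=np.zeros(n),
            R_or_F=dRR,
            valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
            mode="single_channel",
            protocol=protocol,
            dRR=dRR,
        )

    return _make
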