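import numpy as np
import pytest

from pumpwatch import Event, PressureSample, PumpLog, RunLog


def _make_pump_log(pressures, dt=2.0, pump_id=0, rate=1.0, onset_idx=None):
    samples = []
    for i, p in enumerate(pressures):
        ev = Event.OCCLUSION_ONSET if onset_idx is not None and i == onset_idx else Event.NONE
        samples.append(PressureSample(pump_id, i * dt, rate, float(p), ev))
    return PumpLog(pump_id, samples, dt)


@pytest.fixture
def make_log():
    """Factory: build a PumpLog from a pressure array on a dt grid."""
    return _make_pump_log


@pytest.fixture
def make_run():
    """Factory: build a single-pump RunLog from a pressure array."""

    def _make(pressures, dt=2.0, rate=1.0, onset_idx=None, topology=None):
        log = _make_pump_log(pressures, dt=dt, rate=rate, onset_idx=onset_idx)
        return RunLog({0: log}, topology=topology)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
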