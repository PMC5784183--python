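import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import audiosim as asim

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def flat_listener(t, params=None, subject_id="X", age=30.0):
    """Listener with the same true threshold t at every ear and frequency."""
    params = params or asim.DETERMINISTIC
    thresholds = {(ear, f): float(t) for ear in ("left", "right")
                  for f in asim.DEFAULT_GRID}
    return asim.ListenerProfile(
        subject_id, age, thresholds, slope=params.slope,
        lapse_rate=params.lapse_rate, guess_rate=params.guess_rate,
        session_sd=params.session_sd)


def perfect_device(offset=0.0):
    """A device model/instance pair with no unit spread, plus its exact reference."""
    offsets = {f: float(offset) for f in asim.DEFAULT_GRID}
    model = asim.DeviceModel("M", offsets, instance_sd=0.0)
    instance = asim.DeviceInstance("M-0", "M", dict(offsets),
                                   model.min_level, model.max_level)
    reference = asim.ReferenceLevel("M", dict(offsets), 15, 15, True)
    return model, instance, reference


@pytest.fixture
def det_listener():
    return flat_listener(32.5)
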