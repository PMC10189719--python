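import numpy as np
import pytest
from hypothesis import settings

import dichotrack as dt

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trial_set():
    """The standard 28-trial session at 30 Hz."""
    return dt.make_trial_set(0)


@pytest.fixture(scope="session")
def amblyopia_noiseless(trial_set):
    """Noiseless amblyopia-preset observer dataset (delay 0.5 s)."""
    spec = dt.ResponseSpec(noise_sd=0.0, delay=0.5, seed=0)
    return dt.simulate_dataset(dt.PRESETS["amblyopia"], spec, trial_set)


@pytest.fixture(scope="session")
def identity_observer(trial_set):
    """Noiseless, zero-delay observer with an identity model: the
    joystick is an exact rescaling of the summed stimulus contrast."""
    truth = dt.ObserverParams()  # k=1, mu=0, sigma=1
    spec = dt.ResponseSpec(noise_sd=0.0, delay=0.0, seed=0)
    return truth, dt.simulate_dataset(truth, spec, trial_set)


def make_linear_trace(trial, gain, offset, delay):
    """A trace reporting the *binocular stimulus contrast* itself (not a
    model percept) through an affine map and a lag: j = offset +
    gain*C(t-delay), with C held at its start value before trial onset."""
    c = np.interp(trial.t - delay, trial.t, trial.c_left)
    return dt.JoystickTrace(
        trial_id=trial.trial_id, t=trial.t, j=np.clip(offset + gain * c, 0, 1)
    )
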