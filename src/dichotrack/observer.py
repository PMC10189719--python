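"""Synthetic observers: noisy joystick traces from a ground-truth model.

In this paradigm a participant continuously matches a joystick lever to
their perceived contrast. This module emulates that measurement: the
joystick position is a delayed, linearly scaled, noise-corrupted copy
of the model-predicted perceived contrast,

    j(t) = clip_[0,1]( offset + gain * c_hat(t - delay) + eps(t) )

where ``eps`` is zero-mean Gaussian noise low-pass filtered to a motor
bandwidth. This is the forward counterpart of the stage-1 calibration
map fitted by the analysis (an affine map plus a delay), with smooth
band-limited noise standing in for motor/tracking variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .model import ObserverParams, predict_trial
from .stimulus import TrialSet, TrialTimecourse

__all__ = ["ResponseSpec", "JoystickTrace", "simulate_response", "simulate_dataset"]


@dataclass
class ResponseSpec:
    """How a ground-truth percept is turned into a joystick trace.

    ``gain=None`` selects the gain automatically so that the peak
    noiseless response over the simulated trials equals 1 (observers
    were instructed to use the lever's full range); ``offset`` is added
    after scaling; ``delay`` (s) shifts the report in time; ``noise_sd``
    is the standard deviation (joystick units) of additive Gaussian
    noise low-pass filtered at ``noise_bandwidth`` (Hz).
    """

    gain: float | None = None
    offset: float = 0.0
    delay: float = 0.5
    noise_sd: float = 0.05
    noise_bandwidth: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.noise_bandwidth > 0:
            raise ValueError("noise_bandwidth must be > 0")


@dataclass
class JoystickTrace:
    """A sampled joystick position aligned to one trial's time grid."""

    trial_id: int
    t: np.ndarray
    j: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.t)


def _filtered_noise(
    rng: np.random.Generator, n: int, sd: float, bandwidth: float, rate: float
) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    nyq = rate / 2.0
    if bandwidth >= nyq:
        noise = white
    else:
        sos = butter(2, bandwidth, btype="low", fs=rate, output="sos")
        noise = sosfiltfilt(sos, white)
    s = noise.std()
    if s > 0:
        noise = noise * (sd / s)
    return noise


def _noiseless_response(
    truth: ObserverParams, spec: ResponseSpec, trial: TrialTimecourse, gain: float
) -> np.ndarray:
    c_hat = predict_trial(truth, trial)
    if spec.delay > 0:
        # fractional-sample delay via linear interpolation; the percept
        # before trial onset is held at its t=0 value
        c_hat = np.interp(trial.t - spec.delay, trial.t, c_hat)
    return spec.offset + gain * c_hat


def _resolve_gain(
    truth: ObserverParams, spec: ResponseSpec, trials: list[TrialTimecourse]
) -> float:
    if spec.gain is not None:
        return spec.gain
    peak = max(float(np.max(predict_trial(truth, tr))) for tr in trials)
    if peak <= 0:
        raise ValueError("cannot auto-scale gain: model prediction is identically 0")
    return (1.0 - spec.offset) / peak


def simulate_response(
    truth: ObserverParams,
    spec: ResponseSpec,
    trial: TrialTimecourse,
    rng: np.random.Generator | None = None,
) -> JoystickTrace:
    """Simulate one joystick trace for one trial.

    Deterministic given ``spec.seed`` (or an explicit *rng*).
    """
    gain = _resolve_gain(truth, spec, [trial])
    resp = _noiseless_response(truth, spec, trial, gain)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    resp = resp + _filtered_noise(
        rng, trial.n_samples, spec.noise_sd, spec.noise_bandwidth, trial.sample_rate
    )
    return JoystickTrace(trial_id=trial.trial_id, t=trial.t, j=np.clip(resp, 0.0, 1.0))


def simulate_dataset(
    truth: ObserverParams, spec: ResponseSpec, trial_set: TrialSet
) -> list[JoystickTrace]:
    """One trace per trial; the automatic gain is shared across the set
    and each trial draws its noise from an independent substream of
    ``spec.seed``."""
    gain = _resolve_gain(truth, spec, list(trial_set))
    traces = []
    for i, trial in enumerate(trial_set):
        resp = _noiseless_response(truth, spec, trial, gain)
        rng = np.random.default_rng([spec.seed, i])
        resp = resp + _filtered_noise(
            rng, trial.n_samples, spec.noise_sd, spec.noise_bandwidth,
            trial.sample_rate,
        )
        traces.append(
            JoystickTrace(trial_id=trial.trial_id, t=trial.t, j=np.clip(resp, 0.0, 1.0))
        )
    return traces
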