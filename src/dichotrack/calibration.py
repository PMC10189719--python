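"""Stage 1: joystick-to-contrast calibration.

Fits the affine-plus-delay map ``Jhat(t) = a + b * j(t + d)`` that best
reproduces the presented binocular contrast ``C(t)`` over the last 10 s
of every trial's 14-s binocular phase, by mean-squared-error
minimization pooled across trials. ``d`` is the observer's response
lag, so the calibrated percept at time t is read from the joystick d
seconds later. The delay is bounded to [0, 4] s and
the slope to b > 0 (the behaviorally realistic region); the bounds are
enforced by a bounded multi-start optimizer rather than a soft penalty.

Sessions in which the observer used less than 50% of the joystick's
range are excluded before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .exceptions import FitError
from .observer import JoystickTrace
from .stimulus import TrialSet, phase_indices

__all__ = [
    "CalibrationParams",
    "CalibratedTrace",
    "JoystickCalibrator",
    "check_range_usage",
    "fit_calibration",
    "apply_calibration",
]

CALIBRATION_WINDOW = (4.0, 14.0)  #: last 10 s of the binocular phase
DELAY_BOUNDS = (0.0, 4.0)  #: s


@dataclass
class CalibrationParams:
    """Fitted affine map and delay; ``mse`` is the achieved calibration MSE."""

    a: float
    b: float
    d: float
    mse: float


@dataclass
class CalibratedTrace:
    """A joystick trace mapped into contrast units, ``a + b*j(t+d)``.

    Samples whose lag-shifted time falls beyond the trace end are NaN
    and are excluded from all downstream losses.
    """

    trial_id: int
    t: np.ndarray
    j_cal: np.ndarray


@dataclass
class RangeUsage:
    """Result of the 50%-of-joystick-range inclusion check."""

    keep: bool
    fraction: float


def check_range_usage(
    traces: list[JoystickTrace], per_trial: bool = False
) -> RangeUsage | list[RangeUsage]:
    """Apply the exclusion rule: sessions using less than 50% of the
    joystick range are excluded (exactly 50% is kept).

    By default the range is pooled over the whole session; with
    ``per_trial=True`` each trace is checked separately.
    """
    if not traces:
        raise ValueError("check_range_usage requires at least one trace")

    def one(js: np.ndarray) -> RangeUsage:
        frac = float(np.max(js) - np.min(js))
        return RangeUsage(keep=frac >= 0.5, fraction=frac)

    if per_trial:
        return [one(tr.j) for tr in traces]
    return one(np.concatenate([tr.j for tr in traces]))


def _shifted(trace: JoystickTrace, t_eval: np.ndarray, d: float) -> np.ndarray:
    # The observer lags the stimulus by d, so the calibrated estimate of
    # the percept at time t reads the joystick at t + d (fractional-
    # sample shifts via linear interpolation).
    return np.interp(t_eval + d, trace.t, trace.j)


class JoystickCalibrator(BaseEstimator):
    """Stage-1 estimator for the joystick-to-contrast map.

    Parameters
    ----------
    window : (float, float)
        Calibration window in trial time, default the last 10 s of the
        binocular phase.
    delay_step : float
        Spacing of the multi-start grid over the delay, in s.

    Attributes
    ----------
    a_, b_, d_ : float
        Fitted offset, slope and delay.
    mse_ : float
        Achieved mean squared error on the calibration window.
    """

    def __init__(
        self, window: tuple[float, float] = CALIBRATION_WINDOW, delay_step: float = 0.1
    ):
        self.window = window
        self.delay_step = delay_step

    def fit(self, traces: list[JoystickTrace], trial_set: TrialSet):
        pairs = []  # (trace, window times, target contrast)
        for trace, trial in zip(traces, trial_set):
            idx = phase_indices(trial, "binocular", window=self.window)
            if idx.size == 0:
                continue
            # c_left == c_right during the binocular phase by construction
            pairs.append((trace, trial.t[idx], trial.c_left[idx]))
        if not pairs:
            raise FitError("no binocular calibration samples available")
        target = np.concatenate([c for _, _, c in pairs])
        n = target.size

        def affine_sse(d: float) -> tuple[float, float, float]:
            x = np.concatenate([_shifted(tr, tw, d) for tr, tw, _ in pairs])
            sx, sy = x.sum(), target.sum()
            sxx, sxy = x @ x, x @ target
            denom = n * sxx - sx * sx
            if denom <= 1e-12:  # flat joystick: slope unidentifiable
                return np.inf, 0.0, 0.0
            b = (n * sxy - sx * sy) / denom
            if b <= 0:  # outside the allowed region
                return np.inf, 0.0, 0.0
            a = (sy - b * sx) / n
            resid = a + b * x - target
            return float(resid @ resid), a, b

        d_grid = np.arange(DELAY_BOUNDS[0], DELAY_BOUNDS[1] + 1e-9, self.delay_step)
        sses = [affine_sse(d)[0] for d in d_grid]
        i_best = int(np.argmin(sses))
        if not np.isfinite(sses[i_best]):
            raise FitError(
                "calibration failed: no delay admits a positive joystick slope"
            )
        lo = max(DELAY_BOUNDS[0], d_grid[i_best] - self.delay_step)
        hi = min(DELAY_BOUNDS[1], d_grid[i_best] + self.delay_step)
        res = minimize_scalar(
            lambda d: affine_sse(d)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        d_cands = [(sses[i_best], d_grid[i_best])]
        if np.isfinite(res.fun):
            d_cands.append((float(res.fun), float(res.x)))
        sse_best, d_best = min(d_cands)
        _, a, b = affine_sse(d_best)

        self.a_, self.b_, self.d_ = float(a), float(b), float(d_best)
        self.mse_ = sse_best / n
        return self

    def transform(self, traces: list[JoystickTrace]) -> list[CalibratedTrace]:
        params = self.params_
        return [apply_calibration(tr, params) for tr in traces]

    @property
    def params_(self) -> CalibrationParams:
        return CalibrationParams(a=self.a_, b=self.b_, d=self.d_, mse=self.mse_)


def fit_calibration(
    traces: list[JoystickTrace], trial_set: TrialSet, **kwargs
) -> CalibrationParams:
    """Functional wrapper over :class:`JoystickCalibrator`."""
    return JoystickCalibrator(**kwargs).fit(traces, trial_set).params_


def apply_calibration(
    trace: JoystickTrace, params: CalibrationParams
) -> CalibratedTrace:
    """Map one joystick trace into calibrated contrast units.

    The joystick is read at ``t + d`` to undo the response lag; samples
    whose shifted time falls beyond the trace end are NaN (invalid) —
    no post-trial data is fabricated."""
    shifted_t = trace.t + params.d
    j_cal = params.a + params.b * np.interp(shifted_t, trace.t, trace.j)
    j_cal = np.where(shifted_t > trace.t[-1] + 1e-12, np.nan, j_cal)
    return CalibratedTrace(trial_id=trace.trial_id, t=trace.t, j_cal=j_cal)
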