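"""Reliability and efficiency analyses.

* **Split-half reliability**: within each trial the dichoptic
  modulation pattern repeats exactly every 24 s, so the joystick trace
  over [14, 38) s can be correlated with the trace over [38, 62) s.
  Samples falling inside either repeat's monoptic dropout window are
  excluded pairwise, since the dropout breaks the stimulus identity
  between the halves.

* **Reduced dataset**: a shorter session keeping the first 24 trials in
  presentation order, each truncated to its first 38 s (the binocular
  phase plus one full 24-s dichoptic repeat), totalling 912 s of data
  (~15 min). Full- vs reduced-data fits are compared parameter-wise by
  Pearson correlation across observers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import pearsonr

from .binocular import FitResult
from .exceptions import UndefinedStatisticError
from .observer import JoystickTrace
from .stimulus import (
    BINOCULAR_DURATION,
    TrialSet,
    TrialTimecourse,
    dropout_window,
    truncate_trial,
)

__all__ = [
    "ReliabilityReport",
    "ReducedFitComparison",
    "REDUCED_N_TRIALS",
    "REDUCED_DURATION",
    "split_half_reliability",
    "reduce_dataset",
    "compare_fits",
]

REPEAT_DURATION = 24.0  #: s, period after which the dichoptic pattern repeats
REDUCED_N_TRIALS = 24
REDUCED_DURATION = BINOCULAR_DURATION + REPEAT_DURATION  # 38 s

_FIT_PARAMS = ("k_ae", "sigma", "mu_ae", "mu_fe")


@dataclass
class ReliabilityReport:
    """Per-trial split-half correlations for one observer."""

    per_trial_r: np.ndarray
    r: float  #: observer-level mean of the per-trial correlations
    median_r: float
    min_r: float
    max_r: float


@dataclass
class ReducedFitComparison:
    """Parameter-wise Pearson r between full- and reduced-data fits.

    ``r`` maps parameter name -> correlation; parameters whose values
    are constant across observers (correlation undefined) appear in
    ``undefined`` instead of propagating NaN.
    """

    r: dict
    n_observers: int
    undefined: tuple = ()


def _split_half_trial(
    trace: JoystickTrace, trial: TrialTimecourse
) -> float:
    rate = trial.sample_rate
    lag = int(round(REPEAT_DURATION * rate))
    i1 = np.nonzero(
        (trial.t >= BINOCULAR_DURATION) & (trial.t < BINOCULAR_DURATION + REPEAT_DURATION)
    )[0]
    i1 = i1[i1 + lag < trial.n_samples]
    i2 = i1 + lag
    w0, w1 = dropout_window(trial.dropout_cycle_index)
    in_drop = lambda ts: (ts >= w0) & (ts < w1)  # noqa: E731
    # exclude pairs where either repeat's sample sits in the dropout
    keep = ~(in_drop(trial.t[i1]) | in_drop(trial.t[i2]))
    i1, i2 = i1[keep], i2[keep]
    if i1.size < 3:
        raise UndefinedStatisticError(
            f"trial {trial.trial_id}: too few unmasked paired samples"
        )
    a, b = trace.j[i1], trace.j[i2]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError(
            f"trial {trial.trial_id}: constant half, correlation undefined"
        )
    return float(pearsonr(a, b).statistic)


def split_half_reliability(
    traces: list[JoystickTrace], trial_set: TrialSet
) -> ReliabilityReport:
    """Correlate each trial's two stimulus-identical 24-s dichoptic
    repeats and summarize over trials for this observer."""
    rs = np.array(
        [_split_half_trial(tr, trial) for tr, trial in zip(traces, trial_set)]
    )
    return ReliabilityReport(
        per_trial_r=rs,
        r=float(np.mean(rs)),
        median_r=float(np.median(rs)),
        min_r=float(np.min(rs)),
        max_r=float(np.max(rs)),
    )


def reduce_dataset(
    traces: list[JoystickTrace], trial_set: TrialSet
) -> tuple[list[JoystickTrace], TrialSet]:
    """Build the reduced (short-session) dataset: the first
    :data:`REDUCED_N_TRIALS` trials in presentation order, each
    truncated to its first :data:`REDUCED_DURATION` seconds.

    Idempotent; inputs are not mutated.
    """
    keep = min(REDUCED_N_TRIALS, len(trial_set))
    new_trials, new_traces = [], []
    for trial, trace in list(zip(trial_set, traces))[:keep]:
        tt = truncate_trial(trial, REDUCED_DURATION)
        sel = trace.t < REDUCED_DURATION
        new_trials.append(tt)
        new_traces.append(
            replace(trace, t=trace.t[sel], j=trace.j[sel])
        )
    return new_traces, TrialSet(trials=new_trials, order_seed=trial_set.order_seed)


def _param_values(fits: list[FitResult], name: str) -> np.ndarray:
    if name == "k_ae":
        return np.array([f.k_ae_refit for f in fits])
    return np.array([getattr(f.normalization, name) for f in fits])


def compare_fits(
    full: list[FitResult], reduced: list[FitResult]
) -> ReducedFitComparison:
    """Per-parameter Pearson correlation between full- and reduced-data
    fits across the same observers (paired by position)."""
    if len(full) != len(reduced):
        raise ValueError("full and reduced fit lists must be paired")
    if len(full) < 3:
        raise UndefinedStatisticError(
            "need at least 3 paired observers for a correlation"
        )
    r, undefined = {}, []
    for name in _FIT_PARAMS:
        x, y = _param_values(full, name), _param_values(reduced, name)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            undefined.append(name)
            continue
        r[name] = float(pearsonr(x, y).statistic)
    return ReducedFitComparison(
        r=r, n_observers=len(full), undefined=tuple(undefined)
    )
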