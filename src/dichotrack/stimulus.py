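"""Stimulus schedules for the dynamic dichoptic contrast-tracking task.

Each 62-s trial has three phases:

* **binocular** — the first 14 s; both eyes receive identical 1/7 Hz
  sinusoidal contrast modulation (two full cycles).
* **dichoptic** — the remaining 48 s; one eye modulates at 1/6 Hz (8
  cycles) while the other modulates at 1/8 Hz (6 cycles), so the joint
  pattern repeats every 24 s.
* **monoptic** — embedded within the dichoptic span, one eye's modulation
  "drops out" to 0% contrast for exactly one of its own cycles (6 s for
  the 1/6 Hz eye, 8 s for the 1/8 Hz eye) while the other eye continues.

Contrast follows the start-at-zero convention
``C(t) = 0.5 * (1 - cos(2*pi*f*(t - t0)))`` with ``t0`` the start of the
containing phase, so every phase and every cycle begins and ends at zero
contrast and the dropout splices in without a discontinuity.

A full session is 28 trials: every combination of the 2 frequency
assignments (which eye carries 1/6 Hz) and the 14 possible dropped
cycles, presented once in a seeded pseudo-random order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BINOCULAR_DURATION",
    "TRIAL_DURATION",
    "PHASES",
    "TrialTimecourse",
    "TrialSet",
    "make_trial",
    "make_trial_set",
    "phase_indices",
    "dropout_window",
]

TRIAL_DURATION = 62.0  #: s
BINOCULAR_DURATION = 14.0  #: s
BINOCULAR_FREQ = 1.0 / 7.0  #: Hz
FAST_FREQ = 1.0 / 6.0  #: Hz, 8 cycles over the 48-s dichoptic span
SLOW_FREQ = 1.0 / 8.0  #: Hz, 6 cycles over the 48-s dichoptic span
N_FAST_CYCLES = 8
N_SLOW_CYCLES = 6
N_DROPOUT_CYCLES = N_FAST_CYCLES + N_SLOW_CYCLES  # 14
N_TRIALS = 2 * N_DROPOUT_CYCLES  # 28

PHASES = ("binocular", "dichoptic", "monoptic")
EYES = ("left", "right")


@dataclass
class TrialTimecourse:
    """Two-eye contrast schedule for one trial, sampled on a uniform grid.

    Attributes
    ----------
    sample_rate : float
        Samples per second (the task protocol uses 30 Hz).
    t : ndarray
        Time grid in seconds, ``t[k] = k / sample_rate``, half-open
        phase windows ``[start, end)``.
    c_left, c_right : ndarray
        Per-sample contrast in [0, 1] for each eye.
    phase : ndarray of str
        Per-sample label, one of :data:`PHASES`.
    fast_eye : str
        The eye assigned the 1/6 Hz modulation ("left" or "right").
    dropout_eye : str
        The eye whose cycle is zeroed during the monoptic phase.
    dropout_cycle_index : int
        1..14; 1-8 index cycles of the 1/6 Hz eye, 9-14 cycles of the
        1/8 Hz eye, both counted from the start of the dichoptic span.
    trial_id : int
        Position of the trial within its set (0-based), -1 if unset.
    """

    sample_rate: float
    t: np.ndarray
    c_left: np.ndarray
    c_right: np.ndarray
    phase: np.ndarray
    fast_eye: str
    dropout_eye: str
    dropout_cycle_index: int
    trial_id: int = -1

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def contrast(self, eye: str) -> np.ndarray:
        """Contrast series for one physical eye."""
        if eye not in EYES:
            raise ValueError(f"unknown eye {eye!r}")
        return self.c_left if eye == "left" else self.c_right


@dataclass
class TrialSet:
    """An ordered collection of trials (one experimental session)."""

    trials: list[TrialTimecourse] = field(default_factory=list)
    order_seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]


def dropout_window(dropout_cycle_index: int) -> tuple[float, float]:
    """Time window ``[start, end)`` in s of the dropped cycle.

    Cycles are counted per eye from the start of the dichoptic span
    (14 s): indices 1-8 are the 6-s cycles of the 1/6 Hz eye, indices
    9-14 the 8-s cycles of the 1/8 Hz eye.
    """
    i = int(dropout_cycle_index)
    if not 1 <= i <= N_DROPOUT_CYCLES:
        raise ValueError(
            f"dropout_cycle_index must be in 1..{N_DROPOUT_CYCLES}, got {i}"
        )
    if i <= N_FAST_CYCLES:
        period = 1.0 / FAST_FREQ
        start = BINOCULAR_DURATION + period * (i - 1)
    else:
        period = 1.0 / SLOW_FREQ
        start = BINOCULAR_DURATION + period * (i - N_FAST_CYCLES - 1)
    return start, start + period


def _sinusoid(f: float, t: np.ndarray, t0: float) -> np.ndarray:
    # 0 -> 1 -> 0 over each period; starts and ends every cycle at 0.
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * f * (t - t0)))


def make_trial(
    fast_eye: str,
    dropout_cycle_index: int,
    sample_rate: float = 30.0,
    trial_id: int = -1,
) -> TrialTimecourse:
    """Build one trial's contrast schedule.

    Parameters
    ----------
    fast_eye : {"left", "right"}
        The eye that carries the 1/6 Hz modulation; the other eye
        modulates at 1/8 Hz.
    dropout_cycle_index : int
        Which of the 14 possible cycles is dropped (see
        :func:`dropout_window`).
    sample_rate : float
        Samples per second; must be positive.
    """
    if fast_eye not in EYES:
        raise ValueError(f"fast_eye must be 'left' or 'right', got {fast_eye!r}")
    if not sample_rate > 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    w0, w1 = dropout_window(dropout_cycle_index)  # validates the index

    n = int(round(TRIAL_DURATION * sample_rate))
    t = np.arange(n) / sample_rate

    bino = t < BINOCULAR_DURATION
    dich = ~bino
    c_bino = _sinusoid(BINOCULAR_FREQ, t, 0.0)
    c_fast = _sinusoid(FAST_FREQ, t, BINOCULAR_DURATION)
    c_slow = _sinusoid(SLOW_FREQ, t, BINOCULAR_DURATION)

    slow_eye = "right" if fast_eye == "left" else "left"
    per_eye = {fast_eye: c_fast, slow_eye: c_slow}
    c_left = np.where(bino, c_bino, per_eye["left"])
    c_right = np.where(bino, c_bino, per_eye["right"])

    dropout_eye = fast_eye if dropout_cycle_index <= N_FAST_CYCLES else slow_eye
    in_dropout = (t >= w0) & (t < w1)
    if dropout_eye == "left":
        c_left = np.where(in_dropout, 0.0, c_left)
    else:
        c_right = np.where(in_dropout, 0.0, c_right)

    phase = np.full(n, "dichoptic", dtype="<U9")
    phase[bino] = "binocular"
    phase[in_dropout & dich] = "monoptic"

    # clamp tiny negative values from floating-point cosine round-off
    c_left = np.clip(c_left, 0.0, 1.0)
    c_right = np.clip(c_right, 0.0, 1.0)

    return TrialTimecourse(
        sample_rate=float(sample_rate),
        t=t,
        c_left=c_left,
        c_right=c_right,
        phase=phase,
        fast_eye=fast_eye,
        dropout_eye=dropout_eye,
        dropout_cycle_index=int(dropout_cycle_index),
        trial_id=trial_id,
    )


def make_trial_set(order_seed: int, sample_rate: float = 30.0) -> TrialSet:
    """The full 28-trial session: all (frequency assignment, dropped
    cycle) combinations once, shuffled deterministically by *order_seed*."""
    combos = [
        (eye, idx) for eye in EYES for idx in range(1, N_DROPOUT_CYCLES + 1)
    ]
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(combos))
    trials = [
        make_trial(*combos[j], sample_rate=sample_rate, trial_id=i)
        for i, j in enumerate(order)
    ]
    return TrialSet(trials=trials, order_seed=order_seed)


def phase_indices(
    trial: TrialTimecourse,
    phase_label: str,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Sample indices of *trial* carrying *phase_label*.

    Parameters
    ----------
    window : (float, float), optional
        Restrict to times ``window[0] <= t < window[1]`` (e.g. the last
        10 s of the binocular phase, ``(4.0, 14.0)``).
    """
    if phase_label not in PHASES:
        raise ValueError(f"unknown phase label {phase_label!r}")
    mask = trial.phase == phase_label
    if window is not None:
        lo, hi = window
        mask &= (trial.t >= lo) & (trial.t < hi)
    return np.nonzero(mask)[0]


def truncate_trial(trial: TrialTimecourse, duration: float) -> TrialTimecourse:
    """Return a copy of *trial* keeping only samples with ``t < duration``."""
    keep = trial.t < duration
    return replace(
        trial,
        t=trial.t[keep],
        c_left=trial.c_left[keep],
        c_right=trial.c_right[keep],
        phase=trial.phase[keep],
    )
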