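"""Stage 2: monocular attenuation weights from the monoptic phases.

During the monoptic phase only one eye is stimulated, so the reduced
linear model ``Chat = (k_R C_R + k_L C_L) / max(k_R, k_L)`` applies.
The max-normalization makes the solution identifiable: the stronger
eye's weight becomes exactly 1 (the "fellow" eye, FE) and the other
weight, k_ae <= 1, measures relative attenuation of the "amblyopic"
eye (AE). The designation is made by fit, not by clinical label.

Because the pooled objective is exactly quadratic in the single free
weight once the fellow eye is chosen, the fit evaluates both
designations with the closed-form least-squares minimizer (clipped to
(0, 1]) and keeps the one with lower MSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .calibration import CalibratedTrace
from .exceptions import FitError
from .stimulus import TrialSet, phase_indices

__all__ = ["AttenuationFit", "MonocularAttenuationFitter", "fit_attenuation"]

_K_FLOOR = 1e-6


@dataclass
class AttenuationFit:
    """Stage-2 result: per-eye weights after max-normalization.

    Exactly one of ``k_left``/``k_right`` equals 1 (the fellow eye)
    unless the fit is tied, in which case the right eye is designated
    fellow deterministically.
    """

    k_left: float
    k_right: float
    k_ae: float
    ae_eye: str
    mse: float

    @property
    def fe_eye(self) -> str:
        return "right" if self.ae_eye == "left" else "left"


def collect_phase_samples(
    calibrated: list[CalibratedTrace], trial_set: TrialSet, labels: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool (c_left, c_right, calibrated response) over all samples of
    the given phase labels, dropping invalid (NaN) calibrated samples."""
    cl, cr, y = [], [], []
    for trace, trial in zip(calibrated, trial_set):
        idx = np.concatenate(
            [phase_indices(trial, lab) for lab in labels]
        )
        if idx.size == 0:
            continue
        idx.sort()
        valid = ~np.isnan(trace.j_cal[idx])
        idx = idx[valid]
        cl.append(trial.c_left[idx])
        cr.append(trial.c_right[idx])
        y.append(trace.j_cal[idx])
    if not cl:
        return (np.empty(0),) * 3
    return np.concatenate(cl), np.concatenate(cr), np.concatenate(y)


class MonocularAttenuationFitter(BaseEstimator):
    """Stage-2 estimator for the monocular attenuation weights.

    Attributes
    ----------
    k_left_, k_right_ : float
        Max-normalized per-eye weights (one equals 1).
    k_ae_ : float
        The smaller weight, in (0, 1].
    ae_eye_ : str
        The designated amblyopic eye.
    mse_ : float
        MSE over the pooled monoptic samples.
    """

    def __init__(self, tie_tol: float = 1e-9):
        self.tie_tol = tie_tol

    def fit(self, calibrated: list[CalibratedTrace], trial_set: TrialSet):
        cl, cr, y = collect_phase_samples(calibrated, trial_set, ("monoptic",))
        if y.size == 0:
            raise FitError("no monoptic samples available for stage 2")

        def hypothesis(ae_is_left: bool) -> tuple[float, float]:
            c_ae = cl if ae_is_left else cr
            c_fe = cr if ae_is_left else cl
            # minimize sum((y - k*c_ae - c_fe)^2) over k, then clip
            denom = c_ae @ c_ae
            if denom <= 0:
                k = 1.0
            else:
                k = float((y - c_fe) @ c_ae / denom)
            k = float(np.clip(k, _K_FLOOR, 1.0))
            resid = y - k * c_ae - c_fe
            return k, float(resid @ resid / y.size)

        k_l, mse_l = hypothesis(True)
        k_r, mse_r = hypothesis(False)
        # Tie (symmetric observer): designate the right eye as fellow.
        if mse_l <= mse_r + self.tie_tol:
            self.ae_eye_, self.k_ae_, self.mse_ = "left", k_l, mse_l
            self.k_left_, self.k_right_ = k_l, 1.0
        else:
            self.ae_eye_, self.k_ae_, self.mse_ = "right", k_r, mse_r
            self.k_left_, self.k_right_ = 1.0, k_r
        return self

    @property
    def result_(self) -> AttenuationFit:
        return AttenuationFit(
            k_left=self.k_left_,
            k_right=self.k_right_,
            k_ae=self.k_ae_,
            ae_eye=self.ae_eye_,
            mse=self.mse_,
        )


def fit_attenuation(
    calibrated: list[CalibratedTrace], trial_set: TrialSet, **kwargs
) -> AttenuationFit:
    """Functional wrapper over :class:`MonocularAttenuationFitter`."""
    return MonocularAttenuationFitter(**kwargs).fit(calibrated, trial_set).result_
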