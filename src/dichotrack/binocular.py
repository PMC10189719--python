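"""Stage 3: interocular normalization, plus the full three-stage fit.

With the attenuation weight k_ae fixed from stage 2, the normalization
weights (mu_ae, mu_fe) and saturation constant sigma are fitted to the
dichoptic samples by MSE minimization: a coarse grid over the region
0 <= sigma <= 1, 0 <= mu <= 3 selects the start point, and a local
bounded optimizer refines it (sigma and the mu's are bounded below at
~0 but unbounded above, since refined sigma can legitimately exceed
the grid cap). Finally, with the normalization fixed, k_ae is
re-estimated on the full dataset — all monoptic plus dichoptic
samples — under the complete model.

:class:`ThreeStageModel` orchestrates calibration -> attenuation ->
normalization -> re-fit and exposes the result in fitted attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from sklearn.base import BaseEstimator

from .calibration import (
    CalibratedTrace,
    CalibrationParams,
    JoystickCalibrator,
    check_range_usage,
)
from .exceptions import FitError
from .model import ObserverParams
from .monocular import AttenuationFit, MonocularAttenuationFitter, collect_phase_samples
from .observer import JoystickTrace
from .stimulus import TrialSet

__all__ = [
    "NormalizationParams",
    "FitResult",
    "ExclusionRecord",
    "NormalizationFitter",
    "ThreeStageModel",
    "fit_normalization",
    "refit_k",
    "fit_observer",
]

_SIGMA_FLOOR = 1e-6
_K_FLOOR = 1e-6


@dataclass
class NormalizationParams:
    """Stage-3 result on the dichoptic samples."""

    mu_ae: float
    mu_fe: float
    sigma: float
    mse_dichoptic: float


@dataclass
class FitResult:
    """Complete per-observer fit across all three stages."""

    calibration: CalibrationParams
    attenuation: AttenuationFit
    normalization: NormalizationParams
    k_ae_refit: float
    mse_full_before_refit: float
    mse_full: float
    n_samples: dict = field(default_factory=dict)

    @property
    def params(self) -> ObserverParams:
        """The fitted observer as a model parameter set (refit k_ae)."""
        return ObserverParams(
            k_ae=self.k_ae_refit,
            mu_ae=self.normalization.mu_ae,
            mu_fe=self.normalization.mu_fe,
            sigma=self.normalization.sigma,
            ae_eye=self.attenuation.ae_eye,
        )


@dataclass
class ExclusionRecord:
    """Emitted instead of a fit when a session fails the range check."""

    reason: str
    range_fraction: float


def _orient(cl: np.ndarray, cr: np.ndarray, ae_eye: str):
    return (cl, cr) if ae_eye == "left" else (cr, cl)


def _model_mse(
    c_ae: np.ndarray,
    c_fe: np.ndarray,
    y: np.ndarray,
    k_ae: float,
    mu_ae: float,
    mu_fe: float,
    sigma: float,
) -> float:
    pred = k_ae * c_ae / (mu_ae * c_fe + sigma) + c_fe / (mu_fe * k_ae * c_ae + sigma)
    resid = pred - y
    return float(resid @ resid / y.size)


class NormalizationFitter(BaseEstimator):
    """Stage-3 estimator: grid search plus local refinement.

    Parameters
    ----------
    n_sigma, n_mu : int
        Grid resolution over sigma in [0, 1] and each mu in [0, 3].

    Attributes
    ----------
    mu_ae_, mu_fe_, sigma_ : float
        Refined normalization parameters.
    mse_dichoptic_ : float
        Achieved MSE on the pooled dichoptic samples.
    grid_best_ : tuple
        (sigma, mu_ae, mu_fe, mse) at the grid minimum (kept as a
        fallback diagnostic).
    """

    def __init__(self, n_sigma: int = 11, n_mu: int = 16):
        self.n_sigma = n_sigma
        self.n_mu = n_mu

    def fit(
        self,
        calibrated: list[CalibratedTrace],
        trial_set: TrialSet,
        attenuation: AttenuationFit,
        x0: tuple[float, float, float] | None = None,
    ):
        """Fit (sigma, mu_ae, mu_fe) on the dichoptic samples.

        With ``x0 = (sigma, mu_ae, mu_fe)`` the grid search is skipped
        and refinement starts from the supplied point (warm start).
        """
        cl, cr, y = collect_phase_samples(calibrated, trial_set, ("dichoptic",))
        if y.size == 0:
            raise FitError("no dichoptic samples available for stage 3")
        c_ae, c_fe = _orient(cl, cr, attenuation.ae_eye)
        k = attenuation.k_ae

        if x0 is None:
            sigma_grid = np.maximum(np.linspace(0.0, 1.0, self.n_sigma), _SIGMA_FLOOR)
            mu_grid = np.linspace(0.0, 3.0, self.n_mu)

            a_ae = k * c_ae
            best = (np.inf, None)
            # E[i, j] = sum_t (A_i + B_j - y)^2 decomposes into three cheap
            # terms, with the cross term a single matmul per sigma slice.
            for sigma in sigma_grid:
                pa = a_ae[None, :] / (mu_grid[:, None] * c_fe[None, :] + sigma)
                pb = c_fe[None, :] / (mu_grid[:, None] * a_ae[None, :] + sigma)
                da = pa - y[None, :]
                u = np.einsum("it,it->i", da, da)
                v = np.einsum("jt,jt->j", pb, pb)
                w = da @ pb.T
                sse = u[:, None] + v[None, :] + 2.0 * w
                i, j = np.unravel_index(np.argmin(sse), sse.shape)
                if sse[i, j] < best[0]:
                    best = (
                        float(sse[i, j]),
                        (float(sigma), float(mu_grid[i]), float(mu_grid[j])),
                    )
            grid_sse, (s0, ma0, mf0) = best
        else:
            s0, ma0, mf0 = max(x0[0], _SIGMA_FLOOR), max(x0[1], 0.0), max(x0[2], 0.0)
            grid_sse = _model_mse(c_ae, c_fe, y, k, ma0, mf0, s0) * y.size
        self.grid_best_ = (s0, ma0, mf0, grid_sse / y.size)

        def objective(theta: np.ndarray) -> float:
            sigma, mu_ae, mu_fe = theta
            return _model_mse(c_ae, c_fe, y, k, mu_ae, mu_fe, sigma)

        res = minimize(
            objective,
            x0=np.array([s0, ma0, mf0]),
            method="L-BFGS-B",
            bounds=[(_SIGMA_FLOOR, None), (0.0, None), (0.0, None)],
        )
        if res.success and res.fun <= grid_sse / y.size + 1e-15:
            sigma, mu_ae, mu_fe = res.x
            mse = float(res.fun)
        else:
            # fall back to the grid optimum, recorded in grid_best_
            sigma, mu_ae, mu_fe = s0, ma0, mf0
            mse = grid_sse / y.size
        self.sigma_, self.mu_ae_, self.mu_fe_ = float(sigma), float(mu_ae), float(mu_fe)
        self.mse_dichoptic_ = mse
        return self

    @property
    def result_(self) -> NormalizationParams:
        return NormalizationParams(
            mu_ae=self.mu_ae_,
            mu_fe=self.mu_fe_,
            sigma=self.sigma_,
            mse_dichoptic=self.mse_dichoptic_,
        )


def fit_normalization(
    calibrated: list[CalibratedTrace],
    trial_set: TrialSet,
    attenuation: AttenuationFit,
    **kwargs,
) -> NormalizationParams:
    """Functional wrapper over :class:`NormalizationFitter`."""
    return (
        NormalizationFitter(**kwargs).fit(calibrated, trial_set, attenuation).result_
    )


def refit_k(
    calibrated: list[CalibratedTrace],
    trial_set: TrialSet,
    attenuation: AttenuationFit,
    normalization: NormalizationParams,
    k_init: float | None = None,
) -> tuple[float, float]:
    """Re-estimate k_ae on the full dataset (monoptic + dichoptic
    samples) with the normalization parameters held fixed.

    Returns ``(k_ae_refit, mse_full)``. The result never degrades the
    full-data MSE relative to the supplied starting value.
    """
    cl, cr, y = collect_phase_samples(
        calibrated, trial_set, ("monoptic", "dichoptic")
    )
    if y.size == 0:
        raise FitError("no monoptic/dichoptic samples available for k re-estimation")
    c_ae, c_fe = _orient(cl, cr, attenuation.ae_eye)
    mu_ae, mu_fe, sigma = (
        normalization.mu_ae,
        normalization.mu_fe,
        normalization.sigma,
    )

    def objective(k: float) -> float:
        return _model_mse(c_ae, c_fe, y, k, mu_ae, mu_fe, sigma)

    res = minimize_scalar(
        objective, bounds=(_K_FLOOR, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    candidates = [(float(res.fun), float(res.x))]
    if k_init is not None:
        candidates.append((objective(k_init), float(k_init)))
    mse, k = min(candidates)
    return k, mse


class ThreeStageModel(BaseEstimator):
    """The full three-stage fitting pipeline as a single estimator.

    ``fit(traces, trial_set)`` runs calibration (stage 1), monocular
    attenuation (stage 2), interocular normalization (stage 3) and the
    final k_ae re-estimation, pooling samples across all trials.

    Parameters
    ----------
    delay_step : float
        Multi-start grid spacing for the calibration delay (s).
    n_sigma, n_mu : int
        Stage-3 grid resolution.
    range_check : bool
        Enforce the 50%-of-joystick-range inclusion rule before fitting.

    Attributes
    ----------
    calibration_ : CalibrationParams
    attenuation_ : AttenuationFit
    normalization_ : NormalizationParams
    k_ae_refit_ : float
    mse_full_ : float
    params_ : ObserverParams
    result_ : FitResult
    """

    def __init__(
        self,
        delay_step: float = 0.1,
        n_sigma: int = 11,
        n_mu: int = 16,
        range_check: bool = True,
        max_refit_cycles: int = 20,
        refit_tol: float = 1e-6,
    ):
        self.delay_step = delay_step
        self.n_sigma = n_sigma
        self.n_mu = n_mu
        self.range_check = range_check
        self.max_refit_cycles = max_refit_cycles
        self.refit_tol = refit_tol

    def fit(self, traces: list[JoystickTrace], trial_set: TrialSet):
        if self.range_check:
            usage = check_range_usage(traces)
            if not usage.keep:
                raise FitError(
                    "session excluded: joystick range usage "
                    f"{usage.fraction:.3f} < 0.5",
                    ExclusionRecord(
                        reason="range_usage", range_fraction=usage.fraction
                    ),
                )

        calibrator = JoystickCalibrator(delay_step=self.delay_step)
        calibrator.fit(traces, trial_set)
        calibrated = calibrator.transform(traces)

        stage2 = MonocularAttenuationFitter().fit(calibrated, trial_set)
        attenuation = stage2.result_

        stage3 = NormalizationFitter(n_sigma=self.n_sigma, n_mu=self.n_mu)
        stage3.fit(calibrated, trial_set, attenuation)
        normalization = stage3.result_

        # full-data MSE before the re-fit, for the objective-decrease check
        cl, cr, y = collect_phase_samples(
            calibrated, trial_set, ("monoptic", "dichoptic")
        )
        c_ae, c_fe = _orient(cl, cr, attenuation.ae_eye)
        mse_before = _model_mse(
            c_ae, c_fe, y, attenuation.k_ae,
            normalization.mu_ae, normalization.mu_fe, normalization.sigma,
        )
        k_refit, mse_full = refit_k(
            calibrated, trial_set, attenuation, normalization,
            k_init=attenuation.k_ae,
        )
        # Stage 2's reduced model (mu = 0, sigma = 1) biases its k by
        # ~1/sigma, which a single stage-3 + re-fit pass inherits.
        # Alternating the two conditional fits until the full-data MSE
        # stops improving removes that start-point bias; extra cycles
        # are no-ops when the fit is already self-consistent.
        best = (mse_full, k_refit, normalization)
        for _ in range(self.max_refit_cycles):
            prev = mse_full
            att_i = AttenuationFit(
                k_left=k_refit if attenuation.ae_eye == "left" else 1.0,
                k_right=k_refit if attenuation.ae_eye == "right" else 1.0,
                k_ae=k_refit,
                ae_eye=attenuation.ae_eye,
                mse=attenuation.mse,
            )
            stage3.fit(
                calibrated, trial_set, att_i,
                x0=(normalization.sigma, normalization.mu_ae, normalization.mu_fe),
            )
            normalization = stage3.result_
            k_refit, mse_full = refit_k(
                calibrated, trial_set, att_i, normalization, k_init=k_refit
            )
            if mse_full < best[0]:
                best = (mse_full, k_refit, normalization)
            if abs(prev - mse_full) <= self.refit_tol * max(prev, 1e-12):
                break
        mse_full, k_refit, normalization = best

        self.calibration_ = calibrator.params_
        self.attenuation_ = attenuation
        self.normalization_ = normalization
        self.k_ae_refit_ = k_refit
        self.mse_full_ = mse_full
        self.result_ = FitResult(
            calibration=self.calibration_,
            attenuation=attenuation,
            normalization=normalization,
            k_ae_refit=k_refit,
            mse_full_before_refit=mse_before,
            mse_full=mse_full,
            n_samples={"full": int(y.size)},
        )
        return self

    @property
    def params_(self) -> ObserverParams:
        return self.result_.params

    def predict(self, trial) -> np.ndarray:
        """Model-predicted perceived contrast for a trial under the
        fitted parameters."""
        from .model import predict_trial

        return predict_trial(self.params_, trial)


def fit_observer(
    traces: list[JoystickTrace], trial_set: TrialSet, **kwargs
) -> FitResult | ExclusionRecord:
    """Run the full pipeline; excluded sessions yield an
    :class:`ExclusionRecord` instead of raising."""
    model = ThreeStageModel(**kwargs)
    try:
        model.fit(traces, trial_set)
    except FitError as err:
        for arg in err.args:
            if isinstance(arg, ExclusionRecord):
                return arg
        raise
    return model.result_
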