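"""Stage-3 normalization fit, k re-estimation, and the full pipeline."""

import numpy as np
import pytest

import dichotrack as dt
from dichotrack.binocular import NormalizationFitter, refit_k
from dichotrack.calibration import CalibrationParams, apply_calibration
from dichotrack.monocular import AttenuationFit, collect_phase_samples


def _exact_calibrated(truth, trial_set, noise_sd=0.0, seed=0):
    peak = max(float(np.max(dt.predict_trial(truth, tr))) for tr in trial_set)
    spec = dt.ResponseSpec(
        gain=1.0 / peak, offset=0.0, delay=0.0, noise_sd=noise_sd, seed=seed
    )
    traces = dt.simulate_dataset(truth, spec, trial_set)
    cal = CalibrationParams(a=0.0, b=peak, d=0.0, mse=0.0)
    return [apply_calibration(tr, cal) for tr in traces]


def _att(k, ae_eye="left"):
    return AttenuationFit(
        k_left=k if ae_eye == "left" else 1.0,
        k_right=k if ae_eye == "right" else 1.0,
        k_ae=k, ae_eye=ae_eye, mse=0.0,
    )


class TestFitNormalization:
    def test_recovery_with_k_supplied_at_truth(self, trial_set):
        """Exact model match: noiseless traces, exact calibration and
        the true k give back (mu_ae, mu_fe, sigma) almost exactly."""
        truth = dt.PRESETS["amblyopia"]
        calibrated = _exact_calibrated(truth, trial_set)
        norm = dt.fit_normalization(calibrated, trial_set, _att(truth.k_ae))
        assert norm.mu_ae == pytest.approx(truth.mu_ae, abs=0.02)
        assert norm.mu_fe == pytest.approx(truth.mu_fe, abs=0.02)
        assert norm.sigma == pytest.approx(truth.sigma, abs=0.02)
        assert norm.mse_dichoptic < 1e-8

    def test_zero_mu_truth_reduces_to_linear_model(self, trial_set):
        truth = dt.ObserverParams(k_ae=0.5, mu_ae=0, mu_fe=0, sigma=1)
        calibrated = _exact_calibrated(truth, trial_set)
        norm = dt.fit_normalization(calibrated, trial_set, _att(0.5))
        assert norm.mu_ae == pytest.approx(0.0, abs=1e-3)
        assert norm.mu_fe == pytest.approx(0.0, abs=1e-3)
        assert norm.sigma == pytest.approx(1.0, abs=1e-3)

    def test_refined_sigma_can_exceed_the_grid_cap(self, trial_set):
        """The strabismus preset has sigma = 1.23 > 1; refinement is
        unbounded above and must escape the grid's [0, 1] range."""
        truth = dt.PRESETS["strabismus"]
        calibrated = _exact_calibrated(truth, trial_set)
        norm = dt.fit_normalization(calibrated, trial_set, _att(truth.k_ae))
        assert norm.sigma > 1.0
        assert norm.sigma == pytest.approx(1.23, abs=0.02)


class TestRefitK:
    def test_recovers_truth_when_correctly_specified(self, trial_set):
        truth = dt.PRESETS["amblyopia"]
        calibrated = _exact_calibrated(truth, trial_set)
        norm = dt.NormalizationParams(
            mu_ae=truth.mu_ae, mu_fe=truth.mu_fe, sigma=truth.sigma, mse_dichoptic=0.0
        )
        k, mse = refit_k(calibrated, trial_set, _att(truth.k_ae), norm)
        assert k == pytest.approx(truth.k_ae, abs=0.01)

    def test_zero_mu_normalization_reproduces_stage2(self, trial_set):
        truth = dt.ObserverParams(k_ae=0.5, mu_ae=0, mu_fe=0, sigma=1)
        calibrated = _exact_calibrated(truth, trial_set)
        stage2 = dt.fit_attenuation(calibrated, trial_set)
        norm = dt.NormalizationParams(mu_ae=0, mu_fe=0, sigma=1, mse_dichoptic=0.0)
        k, _ = refit_k(calibrated, trial_set, stage2, norm)
        assert k == pytest.approx(stage2.k_ae, abs=1e-4)

    def test_matches_brute_force_grid_on_decimated_data(self):
        ts = dt.TrialSet(
            trials=[dt.make_trial(eye, i, sample_rate=5, trial_id=n)
                    for n, (eye, i) in enumerate(
                        [("left", 1), ("left", 9), ("right", 3), ("right", 12)])]
        )
        truth = dt.PRESETS["amblyopia"]
        calibrated = _exact_calibrated(truth, ts, noise_sd=0.0)
        norm = dt.NormalizationParams(
            mu_ae=2.5, mu_fe=0.3, sigma=1.1, mse_dichoptic=0.0
        )  # deliberately off-truth: the oracle defines the optimum
        k_fit, _ = refit_k(calibrated, ts, _att(truth.k_ae), norm)

        cl, cr, y = collect_phase_samples(calibrated, ts, ("monoptic", "dichoptic"))
        ks = np.arange(0.001, 1.0001, 0.001)
        mses = [
            np.mean(
                (k * cl / (norm.mu_ae * cr + norm.sigma)
                 + cr / (norm.mu_fe * k * cl + norm.sigma) - y) ** 2
            )
            for k in ks
        ]
        assert k_fit == pytest.approx(ks[int(np.argmin(mses))], abs=0.001)


class TestFitObserver:
    @pytest.mark.parametrize("preset", ["control", "amblyopia", "strabismus"])
    def test_end_to_end_noiseless_recovery(self, trial_set, preset):
        """Full pipeline (fitted calibration included) on a noiseless
        preset observer recovers all seven parameters.

        The mu tolerances are wider than in the exact-calibration test:
        the affine stage-1 map cannot invert the compressive binocular
        percept exactly, leaving a small irreducible offset that the
        normalization weights partially absorb (largest for strong
        suppression, ~0.4 in mu_ae for the amblyopia means)."""
        truth = dt.PRESETS[preset]
        spec = dt.ResponseSpec(noise_sd=0.0, delay=0.5, seed=0)
        traces = dt.simulate_dataset(truth, spec, trial_set)
        fit = dt.fit_observer(traces, trial_set)
        assert isinstance(fit, dt.FitResult)
        assert fit.calibration.d == pytest.approx(0.5, abs=0.05)
        p = fit.params
        assert p.ae_eye == truth.ae_eye
        assert p.k_ae == pytest.approx(truth.k_ae, abs=0.05)
        assert p.sigma == pytest.approx(truth.sigma, abs=0.15)
        assert p.mu_ae == pytest.approx(truth.mu_ae, abs=0.5)
        assert p.mu_fe == pytest.approx(truth.mu_fe, abs=0.5)

    def test_invariant_to_trial_order(self, trial_set, amblyopia_noiseless):
        fit = dt.fit_observer(amblyopia_noiseless, trial_set)
        order = np.random.default_rng(3).permutation(28)
        ts2 = dt.TrialSet(trials=[trial_set[i] for i in order])
        fit2 = dt.fit_observer([amblyopia_noiseless[i] for i in order], ts2)
        # pooled objectives: identical up to float summation order
        for name in ("k_ae", "mu_ae", "mu_fe", "sigma"):
            assert getattr(fit2.params, name) == pytest.approx(
                getattr(fit.params, name), abs=1e-4
            )
        assert fit2.params.ae_eye == fit.params.ae_eye

    def test_refit_never_degrades_full_data_mse(self, trial_set):
        for preset in ("control", "amblyopia"):
            spec = dt.ResponseSpec(noise_sd=0.05, seed=9)
            traces = dt.simulate_dataset(dt.PRESETS[preset], spec, trial_set)
            fit = dt.fit_observer(traces, trial_set)
            assert fit.mse_full <= fit.mse_full_before_refit + 1e-12

    def test_narrow_range_session_yields_exclusion_record(self, trial_set):
        squashed = [
            dt.JoystickTrace(tr.trial_id, tr.t, 0.4 + 0.1 * np.sin(tr.t))
            for tr in trial_set
        ]
        out = dt.fit_observer(squashed, trial_set)
        assert isinstance(out, dt.ExclusionRecord)
        assert out.range_fraction < 0.5


def test_recovery_error_grows_with_tracking_noise(trial_set):
    """Noise ablation: with the measurement map inverted exactly (so no
    calibration bias confounds the comparison), the aggregate median
    parameter-recovery error is non-decreasing in the noise SD."""
    truth = dt.PRESETS["amblyopia"]
    peak = max(float(np.max(dt.predict_trial(truth, tr))) for tr in trial_set)
    cal = CalibrationParams(a=0.0, b=peak, d=0.0, mse=0.0)
    totals = []
    for sd in (0.0, 0.02, 0.05, 0.1):
        errs = []
        for seed in range(10):
            spec = dt.ResponseSpec(
                gain=1 / peak, offset=0.0, delay=0.0, noise_sd=sd, seed=seed
            )
            traces = dt.simulate_dataset(truth, spec, trial_set)
            calibrated = [apply_calibration(tr, cal) for tr in traces]
            att = dt.fit_attenuation(calibrated, trial_set)
            norm = dt.fit_normalization(calibrated, trial_set, att)
            k, _ = refit_k(calibrated, trial_set, att, norm, k_init=att.k_ae)
            att2 = _att(k, att.ae_eye)
            norm = dt.fit_normalization(calibrated, trial_set, att2)
            k, _ = refit_k(calibrated, trial_set, att2, norm, k_init=k)
            errs.append(
                [abs(k - truth.k_ae), abs(norm.sigma - truth.sigma),
                 abs(norm.mu_ae - truth.mu_ae), abs(norm.mu_fe - truth.mu_fe)]
            )
        totals.append(float(np.median(errs, axis=0).sum()))
    assert np.all(np.diff(totals) >= 0), totals


def test_no_tradeoff_between_attenuation_and_suppression(trial_set):
    """Across a cohort with independently drawn k_ae and mu_ae, the
    fitted values must not trade off (|r| <= 0.3 at noise 0.05)."""
    rng = np.random.default_rng(2024)
    n = 16
    k_true = rng.uniform(0.3, 1.0, n)
    mu_true = rng.uniform(0.0, 3.0, n)
    ks, mus = [], []
    for i in range(n):
        truth = dt.ObserverParams(
            k_ae=k_true[i], mu_ae=mu_true[i],
            mu_fe=rng.uniform(0, 1), sigma=rng.uniform(0.9, 1.3),
        )
        spec = dt.ResponseSpec(noise_sd=0.05, seed=1000 + i)
        traces = dt.simulate_dataset(truth, spec, trial_set)
        fit = dt.fit_observer(traces, trial_set)
        ks.append(fit.params.k_ae)
        mus.append(fit.params.mu_ae)
    r = np.corrcoef(ks, mus)[0, 1]
    assert abs(r) <= 0.3
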