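"""Split-half reliability and the reduced-dataset comparison."""

import numpy as np
import pytest

import dichotrack as dt
from dichotrack.calibration import CalibrationParams
from dichotrack.evaluation import REDUCED_DURATION, REDUCED_N_TRIALS
from dichotrack.exceptions import UndefinedStatisticError
from dichotrack.monocular import AttenuationFit


class TestSplitHalfReliability:
    def test_noiseless_observer_is_perfectly_reliable(self, trial_set):
        spec = dt.ResponseSpec(noise_sd=0.0, delay=0.0)
        traces = dt.simulate_dataset(dt.PRESETS["amblyopia"], spec, trial_set)
        rep = dt.split_half_reliability(traces, trial_set)
        assert rep.r == pytest.approx(1.0, abs=1e-9)
        assert rep.min_r == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_traces_are_uncorrelated(self, trial_set):
        rng = np.random.default_rng(0)
        traces = [
            dt.JoystickTrace(tr.trial_id, tr.t, rng.random(tr.n_samples))
            for tr in trial_set
        ]
        rep = dt.split_half_reliability(traces, trial_set)
        assert abs(rep.r) < 0.1  # n >= 500 paired samples per trial

    def test_reliability_decreases_with_noise(self, trial_set):
        meds = []
        for sd in (0.02, 0.05, 0.1):
            spec = dt.ResponseSpec(noise_sd=sd, delay=0.0, seed=4)
            traces = dt.simulate_dataset(dt.PRESETS["control"], spec, trial_set)
            meds.append(dt.split_half_reliability(traces, trial_set).median_r)
        assert meds[0] > meds[1] > meds[2]

    def test_constant_trace_is_flagged_undefined(self, trial_set):
        traces = [
            dt.JoystickTrace(tr.trial_id, tr.t, np.full(tr.n_samples, 0.5))
            for tr in trial_set
        ]
        with pytest.raises(UndefinedStatisticError):
            dt.split_half_reliability(traces, trial_set)


class TestReduceDataset:
    def test_shape_matches_the_short_session(self, trial_set, amblyopia_noiseless):
        red_traces, red_set = dt.reduce_dataset(amblyopia_noiseless, trial_set)
        assert len(red_set) == REDUCED_N_TRIALS == 24
        assert all(tr.duration == pytest.approx(38.0) for tr in red_set)
        total = sum(tr.duration for tr in red_set)
        assert total == pytest.approx(24 * 38.0)  # 912 s ~ 15 min
        assert all(
            trc.n_samples == tr.n_samples for trc, tr in zip(red_traces, red_set)
        )

    def test_each_trial_keeps_binocular_and_dichoptic_samples(
        self, trial_set, amblyopia_noiseless
    ):
        _, red_set = dt.reduce_dataset(amblyopia_noiseless, trial_set)
        for tr in red_set:
            assert dt.phase_indices(tr, "binocular").size == 14 * 30
            assert dt.phase_indices(tr, "dichoptic").size > 0
        # the pool retains monoptic data for stage 2
        assert any(dt.phase_indices(tr, "monoptic").size for tr in red_set)

    def test_idempotent_and_non_mutating(self, trial_set, amblyopia_noiseless):
        n0 = trial_set[0].n_samples
        once = dt.reduce_dataset(amblyopia_noiseless, trial_set)
        twice = dt.reduce_dataset(*once)
        assert trial_set[0].n_samples == n0  # inputs untouched
        assert len(twice[1]) == len(once[1])
        for a, b in zip(once[0], twice[0]):
            np.testing.assert_array_equal(a.j, b.j)

    def test_reduced_fit_is_close_to_full_fit(self, trial_set, amblyopia_noiseless):
        full = dt.fit_observer(amblyopia_noiseless, trial_set)
        red = dt.fit_observer(*dt.reduce_dataset(amblyopia_noiseless, trial_set))
        assert red.params.k_ae == pytest.approx(full.params.k_ae, abs=0.05)
        assert red.params.sigma == pytest.approx(full.params.sigma, abs=0.15)


def _fake_fit(k, mu_ae, mu_fe, sigma):
    return dt.FitResult(
        calibration=CalibrationParams(0, 1, 0, 0),
        attenuation=AttenuationFit(k, 1, k, "left", 0),
        normalization=dt.NormalizationParams(mu_ae, mu_fe, sigma, 0),
        k_ae_refit=k,
        mse_full_before_refit=0.0,
        mse_full=0.0,
    )


class TestCompareFits:
    def test_identical_fit_sets_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        fits = [
            _fake_fit(rng.uniform(0.2, 1), rng.uniform(0, 3), rng.uniform(0, 1),
                      rng.uniform(0.8, 1.3))
            for _ in range(6)
        ]
        comp = dt.compare_fits(fits, fits)
        assert comp.n_observers == 6
        for name in ("k_ae", "sigma", "mu_ae", "mu_fe"):
            assert comp.r[name] == pytest.approx(1.0)

    def test_constant_column_is_flagged_not_nan(self):
        fits = [_fake_fit(0.5, mu, 0.3, 1.0) for mu in (0.1, 0.9, 2.2)]
        comp = dt.compare_fits(fits, fits)
        assert "k_ae" in comp.undefined and "mu_fe" in comp.undefined
        assert "mu_ae" in comp.r and not any(
            np.isnan(v) for v in comp.r.values()
        )

    def test_too_few_observers_raise(self):
        fits = [_fake_fit(0.5, 1, 0.3, 1.0)] * 2
        with pytest.raises(UndefinedStatisticError):
            dt.compare_fits(fits, fits)

    def test_attenuation_better_determined_than_fellow_suppression(self, trial_set):
        """Across a noisy cohort, full-vs-reduced correspondence is
        higher for k_ae than for mu_fe (attenuation is pinned by the
        monoptic phases; fellow-eye suppression is the weakest-
        constrained parameter)."""
        rng = np.random.default_rng(7)
        full_fits, red_fits = [], []
        for i in range(10):
            truth = dt.ObserverParams(
                k_ae=rng.uniform(0.3, 1.0),
                mu_ae=rng.uniform(0, 3),
                mu_fe=rng.uniform(0, 1),
                sigma=rng.uniform(0.9, 1.3),
            )
            spec = dt.ResponseSpec(noise_sd=0.05, seed=300 + i)
            traces = dt.simulate_dataset(truth, spec, trial_set)
            full_fits.append(dt.fit_observer(traces, trial_set))
            red_fits.append(dt.fit_observer(*dt.reduce_dataset(traces, trial_set)))
        comp = dt.compare_fits(full_fits, red_fits)
        assert comp.r["k_ae"] > 0.9
        assert comp.r["k_ae"] > comp.r["mu_fe"]
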