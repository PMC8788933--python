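"""Tuning-curve machinery: dF/F, Gaussian fits, OSI, responsiveness,
Gaussian-noise spike model."""

import numpy as np
import pytest

from neurocost import tuning


class TestAngularMetrics:
    def test_ori_periodicity_exhaustive(self):
        x = np.arange(-360.0, 361.0, 1.0)
        assert np.allclose(tuning.ang_ori(x), tuning.ang_ori(x + 180.0))
        assert tuning.ang_ori(x).max() <= 90.0

    def test_dir_periodicity(self):
        x = np.arange(-360.0, 361.0, 1.0)
        assert np.allclose(tuning.ang_dir(x), tuning.ang_dir(x + 360.0))
        assert tuning.ang_dir(x).max() <= 180.0

    def test_reference_values(self):
        assert tuning.ang_ori(170.0) == pytest.approx(10.0)
        assert tuning.ang_dir(190.0) == pytest.approx(170.0)


class TestDff:
    def test_constant_trace_near_zero(self):
        x = np.full(600, 500.0)
        out = tuning.dff(x, fs_hz=30.0)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = 300.0 + 50.0 * rng.random(800)
        a = tuning.dff(x, 30.0)
        b = tuning.dff(3.7 * x, 30.0)
        assert np.allclose(a, b, atol=1e-9)

    def test_recovers_slow_modulation(self):
        fs = 30.0
        t = np.arange(2400) / fs
        s = 0.5 * np.exp(-((t - 40) ** 2) / 18.0)  # slow positive transient
        x = 200.0 * (1.0 + s)
        out = tuning.dff(x, fs)
        assert np.max(np.abs(out - s)) < 0.05

    def test_low_sampling_rejected(self):
        with pytest.raises(ValueError):
            tuning.dff(np.ones(300), fs_hz=1.0)


class TestCalciumResponse:
    def test_flat_trace_zero(self):
        x = np.zeros(400)
        assert tuning.calcium_grating_response(x, 30.0, 5.0) == 0.0

    def test_boxcar_height_recovered(self):
        fs = 30.0
        x = np.zeros(int(12 * fs))
        i0 = int(5 * fs)
        x[i0 : i0 + int(3 * fs)] = 0.8  # 3 s boxcar covers a full 2 s window
        assert tuning.calcium_grating_response(x, fs, 5.0) == pytest.approx(0.8)

    def test_sliding_max_dominates_fixed_window(self):
        rng = np.random.default_rng(1)
        fs = 30.0
        x = rng.normal(0, 0.2, int(12 * fs))
        best = tuning.calcium_grating_response(x, fs, 5.0)
        i0 = int(5 * fs)
        fixed = x[i0 : i0 + int(2 * fs)].mean() - x[i0 - int(fs) : i0].mean()
        assert best >= fixed - 1e-12

    def test_bounds_error(self):
        with pytest.raises(IndexError):
            tuning.calcium_grating_response(np.zeros(100), 30.0, 2.0)


def _gauss_responses(thetas, c, rp, pref, sigma):
    d = tuning.ang_ori(thetas - pref)
    return c + rp * np.exp(-(d**2) / (2 * sigma**2))


class TestOrientationFit:
    thetas = np.arange(0.0, 180.0, 15.0)

    def test_noiseless_width_recovered(self):
        r = _gauss_responses(self.thetas, 0.0, 1.0, 45.0, 25.0)
        fit = tuning.fit_orientation_gaussian(self.thetas, r)
        assert fit.width_deg == pytest.approx(25.0, abs=0.1)
        assert fit.theta_pref_deg == pytest.approx(45.0, abs=0.5)

    def test_wraparound_peak_near_edge(self):
        r = _gauss_responses(self.thetas, 0.0, 1.0, 85.0, 20.0)
        fit = tuning.fit_orientation_gaussian(self.thetas, r)
        assert tuning.ang_ori(fit.theta_pref_deg - 85.0) < 2.0
        # prediction respects 180-degree wrap: -85 and +95 coincide
        assert fit.predict(-85.0) == pytest.approx(fit.predict(95.0))

    def test_generator_broadening_tracked(self):
        """Widening the generating sigma by 1.32x widens the fitted sigma by
        the same factor."""
        r1 = _gauss_responses(self.thetas, 0.0, 1.0, 60.0, 22.0)
        r2 = _gauss_responses(self.thetas, 0.0, 1.0, 60.0, 22.0 * 1.32)
        w1 = tuning.fit_orientation_gaussian(self.thetas, r1).width_deg
        w2 = tuning.fit_orientation_gaussian(self.thetas, r2).width_deg
        assert w2 / w1 == pytest.approx(1.32, abs=0.02)

    def test_width_invariant_to_axis_relabeling(self):
        r = _gauss_responses(self.thetas, 0.0, 1.0, 40.0, 30.0)
        w1 = tuning.fit_orientation_gaussian(self.thetas, r).width_deg
        w2 = tuning.fit_orientation_gaussian(self.thetas - 180.0, r).width_deg
        assert w1 == pytest.approx(w2, rel=1e-6)


class TestDirectionFit:
    dirs = np.arange(0.0, 360.0, 30.0)

    def _double(self, c, rp, rn, pref, sigma):
        d1 = tuning.ang_dir(self.dirs - pref)
        d2 = tuning.ang_dir(self.dirs - pref - 180.0)
        return (
            c
            + rp * np.exp(-(d1**2) / (2 * sigma**2))
            + rn * np.exp(-(d2**2) / (2 * sigma**2))
        )

    def test_noiseless_recovery(self):
        r = self._double(0.0, 1.0, 0.4, 60.0, 28.0)
        fit = tuning.fit_direction_double_gaussian(self.dirs, r)
        assert fit.width_deg == pytest.approx(28.0, abs=0.2)
        assert fit.r_null == pytest.approx(0.4, abs=0.02)
        assert tuning.ang_dir(fit.theta_pref_deg - 60.0) < 2.0

    def test_zero_null_reduces_to_single(self):
        r = self._double(0.0, 1.0, 0.0, 90.0, 25.0)
        fit = tuning.fit_direction_double_gaussian(self.dirs, r)
        assert fit.r_null == pytest.approx(0.0, abs=1e-3)
        assert fit.width_deg == pytest.approx(25.0, abs=0.3)

    def test_symmetric_data_symmetric_amplitudes(self):
        r = self._double(0.0, 1.0, 1.0, 30.0, 30.0)
        fit = tuning.fit_direction_double_gaussian(self.dirs, r)
        assert fit.r_pref == pytest.approx(fit.r_null, rel=0.05)


class TestOSI:
    def test_single_nonzero_response(self):
        assert tuning.osi([0.0, 45.0, 90.0, 135.0], [1.0, 0, 0, 0]) == pytest.approx(
            1.0
        )

    def test_uniform_responses_zero(self):
        th = np.arange(0.0, 180.0, 30.0)
        assert tuning.osi(th, np.ones_like(th)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_complex_arithmetic(self):
        # R = {2 at 0 deg, 1 at 90 deg}: |2 - 1| / 3 = 1/3
        assert tuning.osi([0.0, 90.0], [2.0, 1.0]) == pytest.approx(1.0 / 3.0)

    def test_negative_responses_floored(self):
        assert tuning.osi([0.0, 90.0], [2.0, -1.0]) == pytest.approx(1.0)

    def test_zero_sum_undefined(self):
        with pytest.raises(ValueError):
            tuning.osi([0.0, 90.0], [0.0, 0.0])


class TestBicResponsive:
    dirs = np.arange(0.0, 360.0, 45.0)

    def test_strong_tuning_is_responsive(self):
        d = tuning.ang_dir(self.dirs - 90.0)
        mu = np.exp(-(d**2) / (2 * 30.0**2))
        trials = np.repeat(mu[:, None], 8, axis=1)
        responsive, dbic = tuning.bic_responsive(self.dirs, trials)
        assert responsive
        assert dbic >= 10

    def test_all_zero_not_responsive(self):
        responsive, dbic = tuning.bic_responsive(self.dirs, np.zeros((8, 8)))
        assert not responsive
        assert dbic == 0.0

    def test_false_positive_rate_on_noise(self):
        """Zero-mean Gaussian noise should rarely pass the >= 10 criterion."""
        rng = np.random.default_rng(2)
        fp = 0
        n_runs = 200
        for _ in range(n_runs):
            trials = rng.normal(0.0, 1.0, size=(8, 8))
            responsive, _ = tuning.bic_responsive(self.dirs, trials)
            fp += responsive
        assert fp / n_runs <= 0.05


class TestMovieResponsive:
    def test_deterministic_positive_is_responsive(self):
        x = np.repeat(np.array([0.0, 1.0, 0.0])[:, None], 5, axis=1)
        assert tuning.movie_responsive(x)

    def test_pure_zero_not_responsive(self):
        assert not tuning.movie_responsive(np.zeros((58, 5)))

    def test_injected_bin_above_criterion(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, size=(58, 20))
        x[17] = 5.1 * x[17].std(ddof=1) + 0.0 * x[17]
        assert tuning.movie_responsive(x)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            tuning.movie_responsive(np.zeros((58, 1)))


class TestGaussianNoiseSpikeModel:
    thetas = np.arange(-90.0, 91.0, 15.0)

    def _model(self, cv):
        mu = 0.8 * np.exp(-(self.thetas**2) / (2 * 30.0**2)) + 0.05
        return tuning.SubthresholdTuningModel(self.thetas, mu, cv)

    def test_preferred_is_unity(self):
        p, _ = tuning.gaussian_noise_spike_model(self._model(0.3))
        assert p[np.argmax(np.abs(self.thetas) == 0)] == pytest.approx(1.0)

    def test_symmetric_mu_symmetric_output(self):
        p, _ = tuning.gaussian_noise_spike_model(self._model(0.3))
        assert np.allclose(p, p[::-1], atol=1e-9)

    def test_width_strictly_increasing_in_cv(self):
        widths = [
            tuning.gaussian_noise_spike_model(self._model(cv))[1]
            for cv in (0.15, 0.2, 0.25, 0.3, 0.4)
        ]
        assert np.all(np.diff(widths) > 0)

    def test_zero_cv_degenerate(self):
        with pytest.raises(ValueError):
            tuning.gaussian_noise_spike_model(self._model(0.0))
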