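"""Model-neuron mechanics: passive oracles, reproducibility, convergence,
rheobase structure, stochastic-channel statistics, IF compensation."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import binom, shapiro

from neurocost import biophys


def _passive(mp):
    return replace(mp, gbar_na=0.0, gbar_kv_fast=0.0, gbar_kv_slow=0.0)


class TestPassiveOracle:
    def test_steady_state_matches_closed_form(self, calibrated_model):
        """With all active conductances zero, the steady state under a
        constant synaptic conductance is (gL*EL + g*E)/(gL + g)."""
        mp = _passive(calibrated_model)
        g_ns = 0.15
        g_density = mp.ns_to_density(g_ns)
        n = int(100.0 / 0.025)
        vm = biophys._integrate(
            mp, np.full(n, g_density), np.ones(1), 0.025, e_syn=0.0
        )
        expected = (mp.g_l * mp.e_l + g_density * 0.0) / (mp.g_l + g_density)
        assert vm[0, -1] == pytest.approx(expected, abs=0.005 * abs(expected))

    def test_rheobase_matches_quasistatic_closed_form(self, calibrated_model):
        """Passive model driven by the slow biexponential event: the peak
        tracks the steady state, so the conductance whose peak reaches a
        reference level matches the closed-form g = gL(EL - Vref)/Vref."""
        mp = _passive(calibrated_model)
        v_ref = -50.0
        g_density = mp.g_l * (mp.e_l - v_ref) / v_ref  # solves V_ss = v_ref
        g_ns = g_density * mp.area_cm2 * 1e6
        vm = biophys.simulate_batch(
            mp,
            replace(biophys.SynapticInput(), g_peak_ns=g_ns),
            biophys.NoiseModel("none"),
            1,
            duration_ms=400.0,
            dt_ms=0.05,
        )
        # quasi-static tracking of the slow waveform: within ~3%
        assert vm[0].max() == pytest.approx(v_ref, abs=0.03 * abs(mp.e_l - v_ref))


class TestNumerics:
    def test_deterministic_runs_bit_reproducible(self, calibrated_model, syn):
        a = biophys.simulate_batch(
            calibrated_model, syn, biophys.NoiseModel("none"), 1, duration_ms=100.0
        )
        b = biophys.simulate_batch(
            calibrated_model, syn, biophys.NoiseModel("none"), 1, duration_ms=100.0
        )
        assert np.array_equal(a, b)

    def test_dt_halving_changes_peak_little(self, calibrated_model, rheobases):
        syn = replace(biophys.SynapticInput(), g_peak_ns=0.9 * rheobases["control"])
        v1 = biophys.simulate_batch(
            calibrated_model, syn, biophys.NoiseModel("none"), 1,
            duration_ms=200.0, dt_ms=0.05,
        )[0].max()
        v2 = biophys.simulate_batch(
            calibrated_model, syn, biophys.NoiseModel("none"), 1,
            duration_ms=200.0, dt_ms=0.025,
        )[0].max()
        assert abs(v1 - v2) < 0.1

    def test_external_noise_responses_normal_in_passive_limit(
        self, calibrated_model
    ):
        """At fixed mean drive the external-noise trial responses of the
        passive membrane are Gaussian (Shapiro-Wilk non-rejection)."""
        mp = _passive(calibrated_model)
        g_ns = 0.1
        noise = biophys.NoiseModel("external", sigma0_ns=0.005)
        vm = biophys.simulate_batch(
            mp,
            replace(biophys.SynapticInput(), g_peak_ns=g_ns),
            noise,
            200,
            duration_ms=200.0,
            dt_ms=0.05,
            seed=0,
            g0_ns=g_ns,
        )
        peaks = vm.max(axis=1)
        assert shapiro(peaks).pvalue > 0.01


class TestCalibration:
    def test_control_time_constant_is_ten_ms(self, calibrated_model):
        assert calibrated_model.tau_m_ms == pytest.approx(10.0)

    def test_threshold_in_target_band(self, calibrated_model, syn):
        thr = biophys.spike_threshold(calibrated_model, syn)
        assert -45.0 <= thr <= -38.0

    def test_slow_channel_ablation_preserves_ap_amplitude(
        self, calibrated_model, syn
    ):
        """Removing the slow (noise) channel changes the AP peak by <5% of
        the AP amplitude: the noise source does not reshape spikes."""
        g0 = biophys.find_rheobase(calibrated_model, syn)
        drive = replace(syn, g_peak_ns=1.05 * g0)
        with_slow = biophys.simulate_batch(
            calibrated_model, drive, biophys.NoiseModel("none"), 1
        )[0]
        ablated_mp = replace(calibrated_model, gbar_kv_slow=0.0)
        g0_abl = biophys.find_rheobase(ablated_mp, syn)
        without = biophys.simulate_batch(
            ablated_mp, replace(syn, g_peak_ns=1.05 * g0_abl),
            biophys.NoiseModel("none"), 1,
        )[0]
        rest = biophys.resting_potential(calibrated_model)
        amp = with_slow.max() - rest
        assert abs(with_slow.max() - without.max()) < 0.05 * amp

    def test_markov_backend_not_available(self):
        with pytest.raises(NotImplementedError):
            biophys.ModelParams(nav_backend="markov")


class TestRheobase:
    def test_rheobase_is_threshold_for_spiking(
        self, calibrated_model, syn, rheobases
    ):
        g0 = rheobases["control"]
        above = biophys.simulate_batch(
            calibrated_model, replace(syn, g_peak_ns=g0 * 1.001),
            biophys.NoiseModel("none"), 1,
        )
        below = biophys.simulate_batch(
            calibrated_model, replace(syn, g_peak_ns=g0 * 0.99),
            biophys.NoiseModel("none"), 1,
        )
        assert above.max() >= 0.0
        assert below.max() < 0.0

    def test_food_restricted_rheobase_below_control(self, rheobases):
        assert rheobases["food_restricted"] < rheobases["control"]

    def test_passive_r_only_rheobase_scales_with_leak(self, calibrated_model):
        """In the passive (Ohmic) limit with identical rest and reference
        depolarization, dropping gL to 79% drops the conductance needed for
        a fixed depolarization by the same factor."""
        mp = _passive(calibrated_model)
        mp_r = replace(mp, g_l=mp.g_l * biophys.R_ONLY_GL_FACTOR)
        v_ref = -50.0
        g_ctrl = biophys.matched_gpeak(
            mp, biophys.SynapticInput(), 0.9, mp.e_l, v_ref
        )
        g_r = biophys.matched_gpeak(
            mp_r, biophys.SynapticInput(), 0.9, mp_r.e_l, v_ref
        )
        assert g_r / g_ctrl == pytest.approx(biophys.R_ONLY_GL_FACTOR, rel=0.02)


class TestStochasticChannels:
    def test_stationary_open_counts_binomial(self):
        """Open-channel counts at fixed voltage follow
        Binomial(N, n_inf(V)^4) (chain-update correctness oracle)."""
        v, n_channels = -55.0, 24
        counts = biophys.sample_slow_channel_counts(
            v, n_channels, duration_ms=4000.0, dt_ms=0.01, seed=3
        )
        a, b = biophys._rates_n(v)
        p4 = (a / (a + b)) ** 4
        # subsample beyond the correlation time for near-independent draws
        sub = counts[:: int(5.0 / 0.01)]
        assert sub.mean() == pytest.approx(n_channels * p4, rel=0.2)
        assert sub.var() == pytest.approx(n_channels * p4 * (1 - p4), rel=0.35)

    def test_same_seed_reproducible(self, calibrated_model, syn):
        kw = dict(duration_ms=50.0, seed=11)
        a = biophys.simulate_batch(
            calibrated_model, syn, biophys.NoiseModel("stochastic_channel"), 2, **kw
        )
        b = biophys.simulate_batch(
            calibrated_model, syn, biophys.NoiseModel("stochastic_channel"), 2, **kw
        )
        assert np.array_equal(a, b)


class TestExternalNoiseCV:
    def test_noise_free_cv_zero(self, calibrated_model, syn, rheobases):
        r = biophys.measure_group_cv(
            calibrated_model, syn, biophys.NoiseModel("none"), n_trials=3,
            seed=0, g0_ns=rheobases["control"],
        )
        assert r["cv"] == pytest.approx(0.0, abs=1e-12)

    def test_cv_increases_with_sigma0(self, calibrated_model, syn, rheobases):
        cvs = [
            biophys.measure_group_cv(
                calibrated_model, syn,
                biophys.NoiseModel("external", sigma0_ns=s),
                n_trials=40, seed=1, g0_ns=rheobases["control"],
            )["cv"]
            for s in (0.002, 0.004, 0.008, 0.016, 0.032)
        ]
        assert np.all(np.diff(cvs) > 0)


class TestIOCurve:
    def test_noise_free_is_step_at_rheobase(self, calibrated_model, syn, rheobases):
        io = biophys.run_io_curve(
            calibrated_model, syn, biophys.NoiseModel("none"),
            g_grid=np.array([0.5, 0.9, 1.05, 1.2]), n_trials=1, seed=0,
            g0_ns=rheobases["control"],
        )
        assert np.array_equal(io.p_spike, [0.0, 0.0, 1.0, 1.0])
        assert io.predict(0.5) == pytest.approx(0.0, abs=1e-6)
        assert io.predict(1.1) == pytest.approx(1.0, abs=1e-6)

    def test_noise_smooths_threshold(self, calibrated_model, syn, rheobases):
        io = biophys.run_io_curve(
            calibrated_model, syn,
            biophys.NoiseModel("external", sigma0_ns=0.01),
            g_grid=np.array([0.8, 0.9, 1.0, 1.1]), n_trials=40, seed=2,
            g0_ns=rheobases["control"],
        )
        p_at_rheo = io.p_spike[2]
        assert 0.0 < p_at_rheo < 1.0


class TestIntegrateAndFire:
    def test_zero_input_zero_depolarization(self):
        ifp = biophys.IFParams()
        g0 = biophys.if_rheobase(ifp)
        assert biophys.simulate_if(ifp, 0.0, g0) == 0.0

    def test_rheobase_input_reaches_threshold(self):
        ifp = biophys.IFParams()
        g0 = biophys.if_rheobase(ifp)
        assert biophys.simulate_if(ifp, 1.0, g0) == pytest.approx(1.0, abs=0.01)

    def test_monotone_in_input(self):
        ifp = biophys.IFParams()
        g0 = biophys.if_rheobase(ifp)
        u = [biophys.simulate_if(ifp, f, g0) for f in (0.2, 0.5, 0.8)]
        assert np.all(np.diff(u) > 0)

    def test_compensated_curve_close_to_control(self):
        res = biophys.if_compensation_curves()
        assert res["max_abs_deviation"] < 0.05  # strict 2% bound in acceptance
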