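"""Trace analysis: spikes, subthreshold measures, intrinsic fits,
mEPSC detection and mean-variance analysis."""

import numpy as np
import pytest

from neurocost import ephys, synth


def _vm_with_spikes(n_spikes=7, seed=0):
    tuning = synth.OrientationTuningSpec(pref_deg=0.0, amp_mv=30.0, width_deg=40.0)
    rec = synth.gen_vm_trace(
        tuning,
        trial_cv=0.0,
        v_rest=-70.0,
        v_threshold=-42.0,
        n_trials=1,
        seed=seed,
        dt_ms=0.05,
        orientations_deg=(0.0,),
        ou_sigma_mv=0.0,
    )
    return rec


class TestSpikes:
    def test_flat_trace_empty_train(self):
        train = ephys.detect_spikes(np.full(10000, -70.0), dt_ms=0.05)
        assert len(train) == 0

    def test_detects_inserted_spikes_at_truth_times(self):
        tuning = synth.OrientationTuningSpec(amp_mv=32.0, width_deg=40.0)
        rec = synth.gen_vm_trace(
            tuning, trial_cv=0.0, n_trials=2, seed=3, dt_ms=0.05,
            orientations_deg=(0.0, 60.0), ou_sigma_mv=0.0,
        )
        truth_times = rec.truth.true_params["spike_times_ms"]
        assert truth_times.size > 0
        train = ephys.detect_spikes(rec.trace, rec.dt_ms)
        assert len(train) == truth_times.size
        assert np.all(np.abs(train.spike_times_ms - truth_times) <= 0.5)

    def test_threshold_estimate_near_truth_on_clean_spikes(self):
        rec = _vm_with_spikes()
        train = ephys.detect_spikes(rec.trace, rec.dt_ms)
        assert len(train) > 0
        # inserted spikes kink exactly at the crossing of the true threshold
        assert train.mean_threshold_mv == pytest.approx(-42.0, abs=1.5)

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError):
            ephys.detect_spikes(np.zeros(100), dt_ms=0.2)


class TestSubthreshold:
    def test_no_spikes_identity(self):
        v = np.full(5000, -70.0)
        sub = ephys.extract_subthreshold(v, threshold_mv=-40.0, dt_ms=0.05)
        assert np.array_equal(sub.samples, v)
        assert sub.v_rest_mv == pytest.approx(-70.0)
        assert not sub.quality_warning

    def test_vrest_is_fifth_percentile(self):
        rng = np.random.default_rng(0)
        v = -70.0 + rng.normal(0, 1.0, 20000)
        sub = ephys.extract_subthreshold(v, threshold_mv=0.0, dt_ms=0.05)
        assert sub.v_rest_mv == pytest.approx(np.percentile(v, 5), abs=1e-9)

    def test_median_response_invariant_to_spike_clipping(self):
        """Grating response via the median is unchanged when sparse spikes
        are inserted and then clipped (clipping invariance on paired
        fixtures)."""
        dt = 0.05
        n = int(4000.0 / dt)
        clean = np.full(n, -70.0)
        i0, i1 = int(1000.0 / dt), int(3000.0 / dt)
        clean[i0:i1] = -50.0  # 20 mV depolarization, below -42 mV threshold
        spiky = clean.copy()
        rng = np.random.default_rng(0)
        n_spike = int(round(2.0 / dt))  # 2 ms spikes, ~2% of the window
        for t in rng.integers(i0, i1 - n_spike, size=20):
            spiky[t : t + n_spike] = 10.0
        sub_clean = ephys.extract_subthreshold(clean, -42.0, dt)
        sub_spiky = ephys.extract_subthreshold(spiky, -42.0, dt)
        r1 = ephys.grating_response_vm(sub_clean, (1000.0, 3000.0))
        r2 = ephys.grating_response_vm(sub_spiky, (1000.0, 3000.0))
        assert r1 == pytest.approx(20.0)
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_step_response_measures_five_mv(self):
        dt = 0.1
        v = np.full(40000, -70.0)
        v[20000:] = -65.0  # +5 mV during "grating" at 2000 ms
        sub = ephys.extract_subthreshold(v, 0.0, dt)
        r = ephys.grating_response_vm(sub, (2000.0, 4000.0))
        assert r == pytest.approx(5.0)

    def test_percentile_variant_dominates_median(self):
        rng = np.random.default_rng(1)
        v = -70.0 + rng.normal(0, 2.0, 60000)
        sub = ephys.extract_subthreshold(v, 0.0, 0.05)
        med = ephys.grating_response_vm(sub, (2000.0, 3000.0))
        hi = ephys.grating_response_vm(sub, (2000.0, 3000.0), percentile=95)
        assert hi >= med


class TestTrialCV:
    def test_identical_trials_zero(self):
        assert ephys.trial_cv([3.0, 3.0, 3.0]) == 0.0

    def test_hand_value(self):
        # sample SD of {1,2,3} is 1, mean is 2
        assert ephys.trial_cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        r = np.array([2.0, 3.0, 5.0, 4.0])
        assert ephys.trial_cv(r) == pytest.approx(ephys.trial_cv(10 * r))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            ephys.trial_cv([-1.0, 1.0])


class TestIntrinsic:
    def test_noiseless_exact_recovery(self):
        rec = synth.gen_step_response(150.0, 66.7, noise_sd_mv=0.0, dt_ms=0.1)
        p = ephys.fit_intrinsic_params(rec)
        assert p.r_m_mohm == pytest.approx(150.0, rel=1e-6)
        assert p.tau_m_ms == pytest.approx(150.0 * 66.7 * 1e-3, rel=1e-6)

    def test_cm_identity(self):
        rec = synth.gen_step_response(120.0, 80.0, noise_sd_mv=0.0, dt_ms=0.1)
        p = ephys.fit_intrinsic_params(rec)
        assert p.c_m_pf == pytest.approx(p.tau_m_ms / p.r_m_mohm * 1e3)

    def test_noisy_recovery_within_five_percent(self):
        ests = []
        for s in range(20):
            rec = synth.gen_step_response(
                150.0, 66.7, noise_sd_mv=0.5, seed=s, dt_ms=0.1
            )
            ests.append(ephys.fit_intrinsic_params(rec).r_m_mohm)
        assert np.mean(ests) == pytest.approx(150.0, rel=0.05)


class TestMepscAnalysis:
    def test_zero_event_trace_zero_frequency(self):
        rec = synth.gen_mepsc_recording(
            10, 1.0, event_rate_hz=0.0, duration_s=10.0, baseline_noise_sd_pa=0.0,
            seed=1,
        )
        found = ephys.detect_mepscs(rec)
        assert found.frequency_hz == 0.0

    def test_poisson_rate_recovered(self):
        rec = synth.gen_mepsc_recording(
            100, 0.1, event_rate_hz=1.0, duration_s=300.0,
            baseline_noise_sd_pa=0.3, seed=2,
        )
        found = ephys.detect_mepscs(rec)
        assert found.frequency_hz == pytest.approx(1.0, rel=0.15)

    def test_amplitudes_match_truth(self):
        rec = synth.gen_mepsc_recording(
            100, 0.1, event_rate_hz=0.5, duration_s=120.0,
            baseline_noise_sd_pa=0.2, seed=3,
        )
        found = ephys.detect_mepscs(rec)
        assert found.amplitudes_pa.size > 0
        # truth peak is 10 pA (all 100 channels open at onset)
        assert np.median(found.amplitudes_pa) == pytest.approx(10.0, abs=0.4)

    def test_mean_variance_recovers_channel_parameters(self):
        rec = synth.gen_mepsc_recording(
            100, 1.0, event_rate_hz=5.0, duration_s=120.0,
            baseline_noise_sd_pa=0.5, seed=4,
        )
        found = ephys.detect_mepscs(rec)
        res = ephys.mean_variance_analysis(found)
        assert res.unitary_current_pa == pytest.approx(1.0, rel=0.10)
        assert res.open_channel_number == pytest.approx(100.0, rel=0.20)

    def test_mean_variance_consistency_bias_shrinks(self):
        """Estimator is consistent: unitary-current bias decreases as the
        event count grows."""
        errs = []
        for dur in (30.0, 120.0, 480.0):
            rec = synth.gen_mepsc_recording(
                60, 1.0, event_rate_hz=5.0, duration_s=dur,
                baseline_noise_sd_pa=0.4, seed=5,
            )
            res = ephys.mean_variance_analysis(ephys.detect_mepscs(rec))
            errs.append(abs(res.unitary_current_pa - 1.0))
        assert errs[2] < errs[0] + 0.05
        assert errs[2] < 0.1

    def test_scaled_deterministic_events_give_zero_slope(self):
        """Events that are pure scaled copies of a template (no channel
        noise) produce ~zero variance after peak scaling."""
        dt = 0.1
        t = np.arange(0, 45, dt)
        shape = np.exp(-np.clip(t - 5.0, 0, None) / 5.0) * (t >= 5.0)
        rng = np.random.default_rng(6)
        scales = rng.uniform(8, 12, size=80)
        w = scales[:, None] * shape[None, :]
        events = ephys.MEPSCSet(
            waveforms=w,
            dt_ms=dt,
            peak_index=int(5.0 / dt),
            amplitudes_pa=scales,
            frequency_hz=1.0,
        )
        res = ephys.mean_variance_analysis(events)
        assert abs(res.fit_coeffs[1]) < 1e-9


class TestSynapticEfficacy:
    def test_identical_pulses_ppr_one(self):
        p = np.full(6, 50.0)
        assert ephys.paired_pulse_ratio(p, p) == 1.0

    def test_inv_cv2_hand_value(self):
        rng = np.random.default_rng(7)
        peaks = rng.normal(100.0, 20.0, 5000)
        assert ephys.inv_cv2(peaks) == pytest.approx(25.0, rel=0.1)

    def test_zero_variance_flagged_infinite(self):
        assert ephys.inv_cv2(np.full(25, 10.0)) == np.inf

    def test_minimum_trials(self):
        with pytest.raises(ValueError):
            ephys.paired_pulse_ratio([1.0] * 4, [1.0] * 4)
        with pytest.raises(ValueError):
            ephys.inv_cv2([1.0] * 19)


class TestIOCurveInVivo:
    def test_resting_trace_single_group_no_spikes(self):
        v = np.full(200000, -70.0)
        out = ephys.io_curve_invivo(v, 0.05, threshold_mv=-40.0, v_rest_mv=-70.0)
        assert len(out) == 1
        assert out[0]["group"] == (0.0, 0.1)
        assert out[0]["p_spike"] == 0.0

    def test_constructed_grouping_reproduced(self):
        """Bins placed at known normalized depolarizations fall into the
        expected 0.1-wide groups, and P(spike) matches the constructed
        spiking pattern."""
        dt, bin_ms = 0.1, 100.0
        n_bin = int(bin_ms / dt)
        v_rest, v_thr = -70.0, -40.0
        levels = [0.05, 0.15, 0.15, 0.25, 0.85, 0.85]
        spikes_in = [False, False, True, False, True, True]
        segs = []
        for lev, spk in zip(levels, spikes_in):
            seg = np.full(n_bin, v_rest + lev * (v_thr - v_rest))
            if spk:
                seg[n_bin // 2 : n_bin // 2 + 20] = 10.0  # a clipped spike
            segs.append(seg)
        v = np.concatenate(segs)
        out = ephys.io_curve_invivo(v, dt, v_thr, v_rest)
        by_group = {g["group"][0]: g for g in out}
        assert by_group[0.0]["p_spike"] == 0.0
        assert by_group[0.1]["p_spike"] == pytest.approx(0.5)
        assert by_group[0.2]["p_spike"] == 0.0
        assert by_group[0.8]["p_spike"] == 1.0
        for g in out:
            assert 0.0 <= g["p_spike"] <= 1.0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ephys.io_curve_invivo(np.zeros(1000), 0.1, -80.0, -70.0)
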