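"""Current-clamp feature extraction against analytic spike shapes and the
conductance-based simulator."""

import numpy as np
import pytest

from ephyskit import currentclamp as cc
from ephyskit.simulate.neuron import (NeuronModelParams, StimulusProtocol,
                                      simulate_neuron)
from ephyskit.types import VoltageTrace

FS = 25000.0


def _trace(v, stim=None, fs=FS, vh=-65.0):
    v = np.asarray(v, dtype=float)
    if stim is None:
        stim = np.zeros_like(v)
    return VoltageTrace(fs, v, stim, holding_potential_mv=vh)


def _gaussian_spike(fs=FS, sigma_ms=1.0, peak_mv=35.0, vh=-65.0,
                    duration_ms=40.0):
    t = np.arange(int(duration_ms * 1e-3 * fs)) / fs * 1e3
    center = duration_ms / 2
    v = vh + (peak_mv - vh) * np.exp(-((t - center) ** 2)
                                     / (2 * sigma_ms ** 2))
    return _trace(v, fs=fs, vh=vh), center


class TestRMP:
    def test_constant_trace(self):
        assert cc.measure_rmp(_trace(np.full(5000, -60.0))) == -60.0

    def test_noisy_trace_within_se_of_mean(self):
        rng = np.random.default_rng(0)
        v = -60.0 + rng.normal(0, 1.0, 1000)
        tr = _trace(v, fs=10000.0)  # 100 ms window = all 1000 samples
        assert cc.measure_rmp(tr) == pytest.approx(-60.0, abs=0.1)

    def test_simulated_passive_cell_rests_at_leak_reversal(self):
        p = NeuronModelParams(g_na_ns=0, g_kdr_ns=0, g_m_ns=0, g_bk_ns=0,
                              g_sk_ns=0, leak_reversal_mv=-55.0)
        proto = StimulusProtocol(kind="step_family", step_start_pa=0,
                                 step_stop_pa=0, step_increment_pa=10,
                                 holding_potential_mv=-55.0)
        tr = simulate_neuron(p, proto)[0]
        assert cc.measure_rmp(tr) == pytest.approx(-55.0, abs=0.1)

    def test_stimulus_in_window_rejected(self):
        tr = _trace(np.full(5000, -60.0), stim=np.ones(5000))
        with pytest.raises(ValueError, match="stimulus"):
            cc.measure_rmp(tr)


def _ohmic_sweep(amp_pa, r_gohm=1.0, fs=FS, vh=-65.0):
    n_base, n_step, n_post = int(0.1 * fs), int(0.5 * fs), int(0.1 * fs)
    stim = np.concatenate([np.zeros(n_base), np.full(n_step, amp_pa),
                           np.zeros(n_post)])
    v = vh + stim * r_gohm  # GOhm x pA = mV
    return _trace(v, stim=stim, fs=fs, vh=vh)


class TestInputResistance:
    def test_ideal_ohmic_cell_1gohm(self):
        sweeps = [_ohmic_sweep(a) for a in range(-50, 31, 10) if a != 0]
        assert cc.input_resistance(sweeps) == pytest.approx(1000.0,
                                                            rel=1e-9)

    def test_two_point_line_matches_full_family(self):
        two = [_ohmic_sweep(-50.0), _ohmic_sweep(30.0)]
        assert cc.input_resistance(two) == pytest.approx(1000.0, rel=1e-9)

    def test_simulated_passive_cell_matches_1_over_g(self):
        p = NeuronModelParams(g_na_ns=0, g_kdr_ns=0, g_m_ns=0, g_bk_ns=0,
                              g_sk_ns=0, leak_conductance_ns=1.0,
                              leak_reversal_mv=-65.0)
        sweeps = []
        for a in (-50.0, -30.0, -10.0, 10.0, 30.0):
            proto = StimulusProtocol(kind="step_family", step_start_pa=a,
                                     step_stop_pa=a, step_increment_pa=10)
            sweeps.append(simulate_neuron(p, proto)[0])
        assert cc.input_resistance(sweeps) == pytest.approx(1000.0, abs=10)

    def test_too_few_steps_raise(self):
        with pytest.raises(ValueError, match="usable"):
            cc.input_resistance([_ohmic_sweep(-50.0)])


class TestDetectAPs:
    def test_flat_trace_has_none(self):
        assert cc.detect_aps(_trace(np.full(2500, -65.0))) == []

    def test_single_gaussian_bump_found_at_center(self):
        tr, center_ms = _gaussian_spike()
        peaks = cc.detect_aps(tr)
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(center_ms * 1e-3 * FS, abs=1)

    def test_train_gives_25_peaks_at_20ms_spacing(self, gsk_grid_traces):
        tr = gsk_grid_traces[1.0]
        peaks = cc.detect_aps(tr)
        assert len(peaks) == 25
        isis_ms = np.diff(peaks) / FS * 1e3
        assert np.all(np.abs(isis_ms - 20.0) <= 1.0)

    def test_low_sampling_rate_rejected(self):
        tr = VoltageTrace(5000.0, np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError, match="10 kHz"):
            cc.detect_aps(tr)


class TestThreshold:
    def test_piecewise_kink_at_minus_40(self):
        fs = FS
        dt = 1e3 / fs
        # 2 mV/ms up to -40 mV, then 50 mV/ms to +20, then fall
        seg1 = np.arange(-60.0, -40.0, 2.0 * dt)
        seg2 = np.arange(-40.0, 20.0, 50.0 * dt)
        seg3 = np.arange(20.0, -60.0, -30.0 * dt)
        tr = _trace(np.concatenate([seg1, seg2, seg3]), fs=fs)
        peak = int(np.argmax(tr.voltage_mv))
        assert cc.ap_threshold(tr, peak) == pytest.approx(-40.0, abs=0.5)

    def test_slow_ramp_never_reaches_criterion(self):
        fs = FS
        v = np.linspace(-65.0, -45.0, int(0.02 * fs * 1e3))  # 1 mV/ms
        tr = _trace(v, fs=fs)
        with pytest.raises(cc.NoThresholdError):
            cc.ap_threshold(tr, v.size - 1)

    def test_simulated_ap_threshold_matches_oversampled_scan(self,
                                                             ramp_trace):
        peaks = cc.detect_aps(ramp_trace)
        thr = cc.ap_threshold(ramp_trace, peaks[0])
        # brute force on the same trace: first sample where dV/dt >= 5
        d = cc.dvdt(ramp_trace)
        rising = np.arange(peaks[0] - 50, peaks[0])
        scan = next(ramp_trace.voltage_mv[i] for i in rising
                    if d[i] >= 5.0)
        assert thr == pytest.approx(scan, abs=1.0)


class TestAmplitudeHalfwidth:
    def test_triangular_spike_geometry(self):
        fs = FS
        dt = 1e3 / fs
        rise = np.arange(-65.0, 35.0, 100.0 * dt)       # 1 ms rise
        fall = np.arange(35.0, -65.0, -50.0 * dt)       # 2 ms fall
        tr = _trace(np.concatenate([np.full(100, -65.0), rise, fall]),
                    fs=fs)
        peak = int(np.argmax(tr.voltage_mv))
        amp, hw = cc.ap_amplitude_halfwidth(tr, peak)
        assert amp == pytest.approx(100.0, abs=0.2)
        assert hw == pytest.approx(1.5, abs=2 * dt)

    @pytest.mark.parametrize("sigma_ms", [0.5, 1.0, 2.0])
    def test_gaussian_spike_fwhm_closed_form(self, sigma_ms):
        tr, _ = _gaussian_spike(sigma_ms=sigma_ms)
        peak = int(np.argmax(tr.voltage_mv))
        _, hw = cc.ap_amplitude_halfwidth(tr, peak)
        expect = 2.0 * sigma_ms * np.sqrt(2.0 * np.log(2.0))
        assert hw == pytest.approx(expect, abs=1e3 / FS)

    def test_week3_amplitude_clears_qc_gate(self):
        tr, _ = _gaussian_spike(peak_mv=23.0, vh=-65.0)  # 88 mV amplitude
        peak = int(np.argmax(tr.voltage_mv))
        amp, _ = cc.ap_amplitude_halfwidth(tr, peak)
        assert amp == pytest.approx(88.0, abs=0.1)
        assert cc.apply_qc(-53.5, 900.6, 14.5, amp).passed

    def test_missing_falling_crossing_raises(self):
        v = np.concatenate([np.full(100, -65.0),
                            np.linspace(-65.0, 35.0, 50),
                            np.full(1000, 35.0)])  # never repolarizes
        tr = _trace(v)
        with pytest.raises(ValueError, match="falling"):
            cc.ap_amplitude_halfwidth(tr, int(np.argmax(v)))


class TestFAHP:
    def test_plateau_after_repolarization(self):
        fs = FS
        fall = np.linspace(35.0, -58.0, int(1.0e-3 * fs))
        v = np.concatenate([np.full(50, -65.0),
                            np.linspace(-65, 35, int(0.5e-3 * fs)),
                            fall, np.full(int(8e-3 * fs), -58.0)])
        tr = _trace(v, fs=fs)
        peak = int(np.argmax(v))
        got = cc.fahp(tr, peak)
        assert got == pytest.approx(-58.0, abs=0.5)

    def test_exponential_repolarization_tau_1ms(self):
        fs = FS
        t = np.arange(int(10e-3 * fs)) / fs * 1e3
        decay = -60.0 + 95.0 * np.exp(-t / 1.0)
        v = np.concatenate([np.full(50, -65.0),
                            np.linspace(-65, 35, int(0.5e-3 * fs)), decay])
        tr = _trace(v, fs=fs)
        peak = int(np.argmax(v))
        assert cc.fahp(tr, peak) == pytest.approx(-60.0, abs=0.5)

    def test_band_never_entered_returns_none(self):
        fs = FS
        # keeps falling at 5 mV/ms through the whole window
        v = np.concatenate([np.linspace(-65, 35, int(0.5e-3 * fs)),
                            35.0 - 5.0 * np.arange(int(10e-3 * fs))
                            / fs * 1e3])
        tr = _trace(v, fs=fs)
        assert cc.fahp(tr, int(np.argmax(v))) is None

    def test_simulated_ap_fahp_near_post_peak_minimum(self, ramp_trace):
        peaks = cc.detect_aps(ramp_trace)
        p0 = peaks[0]
        got = cc.fahp(ramp_trace, p0)
        fs = ramp_trace.sampling_rate_hz
        window = ramp_trace.voltage_mv[p0:p0 + int(10e-3 * fs)]
        assert got is not None
        assert abs(got - window.min()) <= 1.0


class TestPostBurstAHP:
    def _train_trace(self, post_fn, fs=FS, vh=-65.0):
        n_base, n_pulse = int(0.05 * fs), int(0.002 * fs)
        period = int(0.02 * fs)
        stim = np.zeros(n_base + 25 * period + int(1.3 * fs))
        for k in range(25):
            i0 = n_base + k * period
            stim[i0:i0 + n_pulse] = 1200.0
        offset = np.nonzero(stim)[0][-1] + 1
        v = np.full(stim.size, vh)
        t_post = np.arange(stim.size - offset) / fs  # s after offset
        v[offset:] = post_fn(t_post)
        return VoltageTrace(fs, v, stim, holding_potential_mv=vh)

    def test_exponential_decay_closed_form(self):
        tr = self._train_trace(lambda t: -65.0 - 5.0 * np.exp(-t / 0.5))
        ahp = cc.post_burst_ahp(tr)
        assert ahp.mahp_mv == pytest.approx(-5.0, abs=0.01)
        assert ahp.sahp_mv == pytest.approx(-5.0 * np.exp(-2.0), abs=0.01)

    def test_flat_post_train_gives_zero(self):
        tr = self._train_trace(lambda t: np.full_like(t, -65.0))
        ahp = cc.post_burst_ahp(tr)
        assert ahp.mahp_mv == 0.0 and ahp.sahp_mv == 0.0

    def test_short_recording_raises(self):
        tr = self._train_trace(lambda t: np.full_like(t, -65.0))
        short = VoltageTrace(tr.sampling_rate_hz,
                             tr.voltage_mv[:int(0.9 * FS)],
                             tr.stimulus_pa[:int(0.9 * FS)],
                             holding_potential_mv=-65.0)
        with pytest.raises(ValueError, match="1.2 s"):
            cc.post_burst_ahp(short)

    def test_sk_conductance_deepens_mahp(self, gsk_grid_traces):
        ahp0 = cc.post_burst_ahp(gsk_grid_traces[0.0])
        ahp2 = cc.post_burst_ahp(gsk_grid_traces[2.0])
        assert abs(ahp2.mahp_mv) > abs(ahp0.mahp_mv)
        assert ahp2.mahp_mv < 0


class TestQC:
    def test_table_row_passes(self):
        assert cc.apply_qc(-53.5, 900.6, 14.5, 88.0).passed

    def test_boundaries_are_strict(self):
        assert not cc.apply_qc(-53.5, 900.6, 30.0, 88.0).passed
        assert not cc.apply_qc(-45.0, 900.6, 14.5, 88.0).passed
        assert not cc.apply_qc(-53.5, 200.0, 14.5, 88.0).passed
        assert not cc.apply_qc(-53.5, 900.6, 14.5, 80.0).passed

    def test_fail_lists_every_violated_gate(self):
        res = cc.apply_qc(-40.0, 100.0, 35.0, 70.0)
        assert not res.passed and len(res.reasons) == 4

    def test_missing_field_is_indeterminate(self):
        res = cc.apply_qc(-53.5, None, 14.5, 88.0)
        assert res.indeterminate and not res.passed

    def test_cohort_pass_rate_matches_row_wise_filtering(self):
        rng = np.random.default_rng(8)
        n = 200
        rs = rng.uniform(10, 40, n)
        rn = rng.uniform(100, 1200, n)
        vr = rng.uniform(-60, -40, n)
        amp = rng.uniform(70, 100, n)
        passes = sum(cc.apply_qc(vr[i], rn[i], rs[i], amp[i]).passed
                     for i in range(n))
        oracle = int(np.sum((rs < 30) & (rn > 200) & (vr < -45)
                            & (amp > 80)))
        assert passes == oracle


class TestResamplingInvariance:
    @pytest.mark.parametrize("fs", [10000.0, 25000.0, 50000.0])
    def test_features_stable_across_sampling_rates(self, fs):
        tr, _ = _gaussian_spike(fs=fs, sigma_ms=1.0)
        peak = int(np.argmax(tr.voltage_mv))
        thr = cc.ap_threshold(tr, peak)
        amp, hw = cc.ap_amplitude_halfwidth(tr, peak)
        ref_hw = 2.0 * np.sqrt(2.0 * np.log(2.0))
        assert hw == pytest.approx(ref_hw, abs=0.1)
        assert amp == pytest.approx(100.0, abs=0.5)
        # threshold of the analytic Gaussian: V where dV/dt first = 5
        assert -66.0 < thr < -30.0
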