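import math

import numpy as np
import pytest

from fluomux import ParameterError
from fluomux.acquisition import RawTraceSet
from fluomux.lockin import (DemodulatedTraceSet, LockInConfig, auto_phase,
                            cascaded_lowpass, demodulate, settle_mask)
from fluomux.optics import cascade_amplitude_response


def _measure_amplitude(out, f, t):
    """Steady-state sinusoid amplitude via quadrature projection over the
    trailing whole periods."""
    period = 1.0 / f
    n_keep = int((t[-1] - t[0]) / (2 * period)) * int(period / (t[1] - t[0]))
    seg, ts = out[-n_keep:], t[-n_keep:]
    c = 2 * np.mean(seg * np.cos(2 * np.pi * f * ts))
    s = 2 * np.mean(seg * np.sin(2 * np.pi * f * ts))
    return math.hypot(c, s)


class TestCascadedLowpass:
    def test_unit_dc_gain(self):
        dt = 1e-5
        out = cascaded_lowpass(np.full(int(0.5 / dt), 3.7), 1e-3, 3, dt)
        assert out[-1] == pytest.approx(3.7, abs=3.7e-6)

    def test_third_order_rolloff_is_18_db_per_octave(self):
        tau, dt = 1e-3, 1e-6
        amps = {}
        for f in (50 / (2 * math.pi * tau), 100 / (2 * math.pi * tau)):
            t = np.arange(int(0.3 / dt)) * dt
            out = cascaded_lowpass(np.cos(2 * np.pi * f * t), tau, 3, dt)
            amps[f] = _measure_amplitude(out, f, t)
        f_lo, f_hi = sorted(amps)
        slope_db = 20 * math.log10(amps[f_lo] / amps[f_hi])
        assert slope_db == pytest.approx(18.06, abs=0.2)

    def test_matches_closed_form_response(self):
        # |H(f)| = (1 + (2 pi f tau)^2)^(-order/2) at 20 log-spaced points
        tau, dt, order = 1e-3, 1e-6, 3
        freqs = np.logspace(1, math.log10(2e4), 20)
        for f in freqs:
            n = int((0.12 + 4 / f) / dt)
            t = np.arange(n) * dt
            out = cascaded_lowpass(np.cos(2 * np.pi * f * t), tau, order, dt)
            expected = float(cascade_amplitude_response(f, tau, order))
            assert _measure_amplitude(out, f, t) == pytest.approx(expected,
                                                                  rel=0.02)

    def test_first_order_half_power_point(self):
        # at f = 1/(2 pi tau), a single stage sits at -3.01 dB
        tau, dt = 1e-3, 1e-6
        f = 1 / (2 * math.pi * tau)
        t = np.arange(int(0.2 / dt)) * dt
        out = cascaded_lowpass(np.cos(2 * np.pi * f * t), tau, 1, dt)
        db = 20 * math.log10(_measure_amplitude(out, f, t))
        assert db == pytest.approx(-3.01, abs=0.03)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            cascaded_lowpass(np.ones(10), -1e-3, 3, 1e-6)
        with pytest.raises(ParameterError):
            cascaded_lowpass(np.ones(10), 1e-3, 0, 1e-6)


class TestDemodulate:
    def test_amplitude_convention_matched_tone(self, tone_raw):
        raw = tone_raw(amplitude=5.0, phase=0.0)
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1e-3,
                          phase_mode="fixed", phase_rad=0.0)
        d = demodulate(raw, [30400.0], cfg)
        _, x = d.valid(d.labels[0])
        assert x[-1] == pytest.approx(5.0, rel=1e-6)

    def test_dc_input_rejected(self, tone_raw):
        raw = tone_raw(amplitude=0.0, dc=7.0)
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1e-3,
                          phase_mode="fixed")
        d = demodulate(raw, [30400.0], cfg)
        _, x = d.valid(d.labels[0])
        assert np.abs(x[-50:]).max() < 1e-6 * 7.0

    def test_two_tone_rejection_matches_cascade_response(self, tone_raw):
        # tones 6.9 kHz apart at tau = 1 ms: |H| = (1 + 43.35^2)^(-3/2)
        f1, f2 = 30400.0, 37300.0
        raw = tone_raw(freq_hz=f1, amplitude=5.0, phase=0.0, duration_s=0.3)
        t = raw.time_s
        y = raw.signals["pmt"] + 1.0 * np.cos(2 * np.pi * f2 * t)
        raw2 = RawTraceSet(t, {"pmt": y}, raw.sim_rate_hz, {})
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1e-3,
                          phase_mode="fixed")
        d = demodulate(raw2, [f1], cfg)
        _, x = d.valid(d.labels[0])
        ripple = np.ptp(x[len(x) // 2:]) / 2
        bound = float(cascade_amplitude_response(f2 - f1, 1e-3, 3))
        assert bound < 1.3e-5
        assert ripple < 3 * bound  # ripple at Delta-f plus image terms

    def test_linearity_exact(self, tone_raw):
        f = 30400.0
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1e-3,
                          phase_mode="fixed")
        r1 = tone_raw(amplitude=2.0, phase=0.4)
        r2 = tone_raw(amplitude=1.0, phase=1.9)
        combined = RawTraceSet(r1.time_s,
                               {"pmt": 3 * r1.signals["pmt"] - 2 * r2.signals["pmt"]},
                               r1.sim_rate_hz, {})
        da = demodulate(r1, [f], cfg)[f"pmt@{f/1000:g}kHz"]
        db_ = demodulate(r2, [f], cfg)[f"pmt@{f/1000:g}kHz"]
        dc = demodulate(combined, [f], cfg)[f"pmt@{f/1000:g}kHz"]
        np.testing.assert_allclose(dc, 3 * da - 2 * db_, rtol=1e-9, atol=1e-9)

    def test_nyquist_guard(self, tone_raw):
        raw = tone_raw()
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1e-3)
        with pytest.raises(ParameterError):
            demodulate(raw, [6.0e5], cfg)

    def test_noninteger_decimation_snaps_with_warning(self, tone_raw, caplog):
        raw = tone_raw(duration_s=0.05)
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1.0345e-3)
        import logging
        with caplog.at_level(logging.WARNING, logger="fluomux"):
            d = demodulate(raw, [30400.0], cfg)
        assert "snapping" in caplog.text
        # snapped to a whole number of simulation steps
        m = round((d.time_s[1] - d.time_s[0]) * raw.sim_rate_hz)
        assert d.time_s[1] - d.time_s[0] == pytest.approx(m / raw.sim_rate_hz,
                                                          abs=1e-12)


class TestAutoPhase:
    def test_round_trip_recovers_generation_phase(self, tone_raw):
        for phi0 in (0.0, 0.7, -2.0):
            raw = tone_raw(amplitude=4.0, phase=phi0)
            phi = auto_phase(raw, "pmt", 30400.0, (0.05, 0.15))
            assert math.remainder(phi - phi0, 2 * math.pi) == pytest.approx(
                0.0, abs=1e-3)

    def test_quadrature_nulled_after_autophase(self, tone_raw):
        raw = tone_raw(amplitude=4.0, phase=1.2)
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1e-3,
                          phase_mode="auto", output_mode="in_phase")
        d = demodulate(raw, [30400.0], cfg)
        _, x = d.valid(d.labels[0])
        assert x[-1] == pytest.approx(4.0, rel=1e-4)  # all signal in X

    def test_pi_shift_flips_in_phase_sign(self, tone_raw):
        cfg = LockInConfig(time_constant_s=1e-3, output_interval_s=1e-3,
                          phase_mode="fixed", phase_rad=0.0)
        x_pos = demodulate(tone_raw(amplitude=3.0, phase=0.0), [30400.0], cfg)
        x_neg = demodulate(tone_raw(amplitude=3.0, phase=math.pi), [30400.0], cfg)
        a = x_pos[x_pos.labels[0]][-1]
        b = x_neg[x_neg.labels[0]][-1]
        assert a == pytest.approx(3.0, rel=1e-6)
        assert b == pytest.approx(-3.0, rel=1e-6)

    def test_short_window_rejected(self, tone_raw):
        raw = tone_raw()
        with pytest.raises(ParameterError):
            auto_phase(raw, "pmt", 30400.0, (0.0, 1e-4))


class TestSettleMask:
    @pytest.mark.parametrize("tau,order,expected_s",
                             [(1e-3, 3, 0.030), (1e-4, 3, 0.003)])
    def test_masked_span(self, tau, order, expected_s):
        cfg = LockInConfig(time_constant_s=tau, output_interval_s=tau,
                          order=order)
        t = np.arange(0, 0.1, tau)
        m = settle_mask(cfg, t)
        assert t[m][-1] < expected_s <= t[~m][0] + tau

    def test_step_reaches_99_percent_within_mask(self):
        tau, order, dt = 1e-3, 3, 1e-6
        cfg = LockInConfig(time_constant_s=tau, output_interval_s=1e-3,
                          order=order)
        t = np.arange(int(0.05 / dt)) * dt
        out = cascaded_lowpass(np.ones_like(t), tau, order, dt)
        settled = out[int(cfg.settle_time_s / dt) - 1]
        assert settled >= 0.99


class TestNoiseScaling:
    def test_output_noise_scales_as_inverse_sqrt_tau(self):
        # white detector noise -> demodulated baseline SD ~ tau^(-1/2)
        rate = 2.5e5
        rng = np.random.default_rng(11)
        t = np.arange(int(2.6 * rate)) / rate
        f = 30400.0
        y = 10.0 + np.cos(2 * np.pi * f * t) + rng.standard_normal(t.size)
        raw = RawTraceSet(t, {"pmt": y}, rate, {})
        sds = {}
        for tau in (1e-4, 1e-3, 1e-2):
            cfg = LockInConfig(time_constant_s=tau, output_interval_s=tau,
                              phase_mode="fixed")
            d = demodulate(raw, [f], cfg)
            _, x = d.valid(d.labels[0])
            sds[tau] = float(np.std(x[:200], ddof=1))
        for tau_a, tau_b in ((1e-4, 1e-3), (1e-3, 1e-2)):
            ratio = sds[tau_a] / sds[tau_b]
            assert ratio == pytest.approx(math.sqrt(10), rel=0.2)
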