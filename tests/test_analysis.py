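import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluomux import FitError, ParameterError
from fluomux.analysis import (ProcessedTrace, calibrate_vm, crosstalk,
                              default_baseline_window, detect_onset, dff0,
                              fit_monoexponential, nernst_potential,
                              ratio_trace, sliding_average, snr,
                              subtract_control, vm_at_onset, vm_from_dff)
from fluomux.kinetics import resact_cascade_fixture, time_grid


@pytest.fixture
def grid():
    return time_grid(3.0, 1e-3)


class TestDff0:
    def test_constant_trace_is_zero_percent(self, grid):
        out = dff0(grid, np.full(grid.size, 4.2), (0.0, 0.01))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_doubling_gives_plus_100_percent(self, grid):
        v = np.where(grid < 1.0, 2.0, 4.0)
        out = dff0(grid, v, (0.0, 0.5))
        assert out.values[-1] == pytest.approx(100.0, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(gain=st.floats(1e-6, 1e6))
    def test_gain_invariance_to_machine_precision(self, gain):
        t = time_grid(1.0, 1e-2)
        rng = np.random.default_rng(0)
        v = 5.0 + np.abs(rng.standard_normal(t.size)) + 0.5
        a = dff0(t, v, (0.0, 0.2)).values
        b = dff0(t, gain * v, (0.0, 0.2)).values
        np.testing.assert_allclose(b, a, rtol=1e-12, atol=1e-12)

    def test_nonpositive_baseline_rejected(self, grid):
        with pytest.raises(ParameterError):
            dff0(grid, np.zeros(grid.size), (0.0, 0.01))

    def test_baseline_must_avoid_settling(self, grid):
        mask = grid < 0.5
        with pytest.raises(ParameterError):
            dff0(grid, np.ones(grid.size), (0.0, 0.1), settling_mask=mask)


class TestSubtractControl:
    def _tr(self, t, v):
        return ProcessedTrace(t, v, "dff_pct")

    def test_self_subtraction_is_zero(self, grid):
        x = self._tr(grid, np.sin(grid))
        out = subtract_control(x, x)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_zero_control_is_identity(self, grid):
        x = self._tr(grid, np.sin(grid))
        out = subtract_control(x, self._tr(grid, np.zeros(grid.size)))
        np.testing.assert_array_equal(out.values, x.values)

    def test_shared_drift_cancels_exactly(self, grid):
        drift = 0.3 * grid
        stim = self._tr(grid, np.sin(grid) + drift)
        ctrl = self._tr(grid, drift)
        out = subtract_control(stim, ctrl)
        np.testing.assert_allclose(out.values, np.sin(grid), atol=1e-12)

    def test_disjoint_ranges_rejected(self, grid):
        a = self._tr(grid, np.ones(grid.size))
        b = self._tr(grid + 10.0, np.ones(grid.size))
        with pytest.raises(ParameterError):
            subtract_control(a, b)


class TestSlidingAverage:
    def test_constant_unchanged(self):
        out = sliding_average(np.full(100, 3.3), window_points=9)
        np.testing.assert_allclose(out, 3.3, atol=1e-12)

    def test_impulse_spreads_to_plateau(self):
        v = np.zeros(101)
        v[50] = 7.0
        out = sliding_average(v, window_points=5)
        np.testing.assert_allclose(out[48:53], 7.0 / 5, atol=1e-12)

    def test_white_noise_sd_reduced_by_sqrt_window(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(200000)
        m = 25
        out = sliding_average(v, window_points=m)
        interior = out[m:-m]
        assert np.std(interior) == pytest.approx(1 / math.sqrt(m), rel=0.05)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ParameterError):
            sliding_average(np.ones(5), window_points=9)


class TestCrosstalk:
    def test_self_crosstalk_is_100_percent(self, grid):
        x = np.sin(2 * np.pi * grid) + 0.2 * grid
        res = crosstalk(x, x, time_s=grid, window_s=(0.0, 2.0))
        assert res.percent == pytest.approx(100.0, rel=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_self_crosstalk_property_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        t = time_grid(1.0, 1e-2)
        x = rng.standard_normal(t.size).cumsum()
        if np.ptp(x) == 0:
            return
        res = crosstalk(x, x, time_s=t)
        assert res.percent == pytest.approx(100.0, rel=1e-9)

    def test_flat_target_is_zero_percent(self, grid):
        x = np.sin(grid)
        res = crosstalk(x, np.zeros(grid.size), time_s=grid)
        assert res.percent == pytest.approx(0.0, abs=1e-9)

    def test_ols_recovers_known_slope(self, grid):
        rng = np.random.default_rng(4)
        src = 10.0 * np.sin(2 * np.pi * grid / 3)
        tgt = 0.31 * src + 0.05 * rng.standard_normal(grid.size)
        res = crosstalk(src, tgt, time_s=grid, window_s=(0.0, 2.0))
        assert res.percent == pytest.approx(31.0, abs=1.0)

    def test_zero_variance_source_rejected(self, grid):
        with pytest.raises(ParameterError):
            crosstalk(np.ones(grid.size), np.sin(grid), time_s=grid)


class TestSnr:
    def test_known_gaussian_snr(self):
        rng = np.random.default_rng(5)
        v = 10.0 + rng.standard_normal(200)
        est = snr(v)
        # mean/SD estimator scatter: within ~2 SE of 10
        assert est == pytest.approx(10.0, abs=2 * 10 / math.sqrt(2 * 199))

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        v = 10.0 + rng.standard_normal(200)
        assert snr(3.7 * v) == pytest.approx(snr(v), rel=1e-12)

    def test_doubling_noise_halves_snr(self):
        rng = np.random.default_rng(7)
        noise = rng.standard_normal(200)
        noise -= noise.mean()  # keep the signal mean fixed
        assert snr(10 + noise) / snr(10 + 2 * noise) == pytest.approx(2.0,
                                                                     rel=1e-9)

    def test_zero_sd_reports_infinite_with_warning(self):
        with pytest.warns(UserWarning):
            assert snr(np.full(200, 5.0)) == math.inf


class TestRatioTrace:
    def test_equal_channels_give_zero(self, grid):
        v = 2.0 + np.sin(grid) ** 2
        out = ratio_trace(grid, v, v, (0.0, 0.05))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(g1=st.floats(1e-3, 1e3), g2=st.floats(1e-3, 1e3))
    def test_per_channel_gain_invariance(self, g1, g2):
        t = time_grid(1.0, 1e-2)
        rng = np.random.default_rng(1)
        num = 3.0 + rng.random(t.size)
        den = 2.0 + rng.random(t.size)
        a = ratio_trace(t, num, den, (0.0, 0.2)).values
        b = ratio_trace(t, g1 * num, g2 * den, (0.0, 0.2)).values
        np.testing.assert_allclose(b, a, rtol=1e-11, atol=1e-9)

    def test_opposed_ten_percent_changes(self, grid):
        num = np.where(grid < 1.0, 1.0, 1.1)
        den = np.where(grid < 1.0, 1.0, 0.9)
        out = ratio_trace(grid, num, den, (0.0, 0.5))
        assert out.values[-1] == pytest.approx((1.1 / 0.9 - 1) * 100, rel=1e-9)

    def test_nonpositive_denominator_rejected_with_index(self, grid):
        den = np.ones(grid.size)
        den[123] = 0.0
        with pytest.raises(ParameterError, match="123"):
            ratio_trace(grid, np.ones(grid.size), den, (0.0, 0.05))


class TestMonoexponentialFit:
    def test_exact_model_recovery(self):
        t = time_grid(0.05, 1e-5)
        y = 2.0 + 3.0 * np.exp(-354.0 * t)
        res = fit_monoexponential(t, y)
        assert res.k_per_s == pytest.approx(354.0, abs=1e-6)
        assert res.amplitude == pytest.approx(3.0, rel=1e-9)
        assert res.offset == pytest.approx(2.0, rel=1e-9)

    def test_noisy_recovery_within_standard_error(self):
        rng = np.random.default_rng(8)
        t = time_grid(0.1, 1e-5)
        y = 1.0 + 2.0 * np.exp(-178.0 * t) + 0.01 * rng.standard_normal(t.size)
        res = fit_monoexponential(t, y)
        assert res.k_per_s == pytest.approx(178.0, abs=3 * res.k_se)

    def test_constant_trace_rejected(self):
        t = time_grid(0.05, 1e-4)
        with pytest.raises((FitError, ParameterError)):
            fit_monoexponential(t, np.full(t.size, 2.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_monoexponential(np.arange(10) * 0.01,
                                np.exp(-np.arange(10) * 0.01))


class TestNernst:
    def test_equal_concentrations_zero_potential(self):
        assert nernst_potential(423.0) == 0.0

    def test_tenfold_gradient_at_18_celsius(self):
        # (R*291.15/F) * ln(0.1) * 1000
        assert nernst_potential(42.3) == pytest.approx(-57.77, abs=0.01)

    def test_log_linearity(self):
        d1 = nernst_potential(100.0) - nernst_potential(10.0)
        d2 = nernst_potential(400.0) - nernst_potential(40.0)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ParameterError):
            nernst_potential(0.0)


class TestVmCalibration:
    def test_noiseless_identity(self):
        ek = np.array([-80.0, -60.0, -40.0, -20.0])
        peaks = 0.5 * (ek - (-45.0))
        cal = calibrate_vm(peaks, ek)
        assert cal.sensitivity_pct_per_mv == pytest.approx(0.5, rel=1e-12)
        assert cal.v_rest_mv == pytest.approx(-45.0, rel=1e-12)

    def test_noisy_recovery_within_two_se(self):
        rng = np.random.default_rng(9)
        ek = np.linspace(-90, -10, 9)
        peaks = 0.5 * (ek + 45.0) + 0.5 * rng.standard_normal(ek.size)
        cal = calibrate_vm(peaks, ek)
        assert cal.sensitivity_pct_per_mv == pytest.approx(
            0.5, abs=2 * cal.sensitivity_se)
        assert cal.v_rest_mv == pytest.approx(-45.0, abs=2 * cal.v_rest_se)

    def test_zero_slope_rejected(self):
        with pytest.raises(ParameterError):
            calibrate_vm(np.zeros(4), np.array([-80.0, -60.0, -40.0, -20.0]))

    def test_vm_conversion_and_sign(self):
        ek = np.array([-80.0, -60.0, -40.0])
        cal = calibrate_vm(0.5 * (ek + 45.0), ek)
        t = time_grid(1.0, 1e-2)
        tr = ProcessedTrace(t, np.where(t < 0.5, 0.0, -5.0), "dff_pct")
        vm = vm_from_dff(tr, cal)
        assert vm.values[0] == pytest.approx(-45.0, rel=1e-9)   # dFF 0 -> V_rest
        assert vm.values[-1] == pytest.approx(-55.0, rel=1e-9)  # hyperpolarized

    def test_round_trip_through_synthetic_peaks(self):
        # generate peaks from a known (sensitivity, V_rest), recalibrate,
        # convert a trace and map back
        s0, v0 = 0.4, -42.0
        ek = np.linspace(-85, -25, 7)
        cal = calibrate_vm(s0 * (ek - v0), ek)
        t = time_grid(1.0, 1e-2)
        v_true = v0 - 20.0 * np.exp(-t)
        dff = (v_true - v0) * cal.sensitivity_pct_per_mv
        back = vm_from_dff(ProcessedTrace(t, dff, "dff_pct"), cal)
        np.testing.assert_allclose(back.values, v_true, rtol=1e-9)


class TestOnset:
    def test_step_onset_located(self):
        t = time_grid(1.0, 1e-3)
        rng = np.random.default_rng(10)
        v = 0.1 * rng.standard_normal(t.size)
        v[t >= 0.4] += 10 * 0.1
        res = detect_onset(t, v, (0.0, 0.1))
        assert res.detected
        assert res.latency_s == pytest.approx(0.4, abs=2e-3)

    def test_flat_noise_gives_no_onset(self):
        t = time_grid(1.0, 1e-3)
        rng = np.random.default_rng(11)
        res = detect_onset(t, rng.standard_normal(t.size), (0.0, 0.1))
        assert not res.detected and res.latency_s is None

    def test_cascade_onsets_preserve_ordering(self):
        t = time_grid(2.0, 1e-3)
        tr = resact_cascade_fixture(t)
        rng = np.random.default_rng(12)
        lat = {}
        for name in ("vm", "ph", "ca"):
            v = tr[name] + 1e-3 * rng.standard_normal(t.size)
            lat[name] = detect_onset(t, v, (0.0, 0.04)).latency_s
        assert lat["vm"] < lat["ph"] < lat["ca"]

    def test_negative_direction_autodetected(self):
        t = time_grid(1.0, 1e-3)
        v = np.where(t < 0.3, 1.0, 0.2) + 1e-6 * np.sin(t)
        res = detect_onset(t, v, (0.0, 0.1))
        assert res.direction == -1
        assert res.latency_s == pytest.approx(0.3, abs=2e-3)


class TestVmAtOnset:
    def test_linear_ramp_interpolation(self):
        t = time_grid(1.0, 1e-2)
        vm = ProcessedTrace(t, -40.0 - 50.0 * t, "mV")
        assert vm_at_onset(vm, 0.2) == pytest.approx(-50.0, rel=1e-9)

    def test_sample_point_exact(self):
        t = time_grid(1.0, 1e-2)
        vm = ProcessedTrace(t, np.sin(t), "mV")
        assert vm_at_onset(vm, float(t[37])) == vm.values[37]

    def test_latency_outside_trace_rejected(self):
        t = time_grid(1.0, 1e-2)
        vm = ProcessedTrace(t, np.zeros(t.size), "mV")
        with pytest.raises(ParameterError):
            vm_at_onset(vm, 5.0)


class TestBaselineWindow:
    def test_skips_settling_mask(self):
        t = time_grid(1.0, 1e-3)
        mask = t < 0.03
        w = default_baseline_window(t, mask, n_points=10)
        assert w[0] >= 0.03
        assert w[1] - w[0] == pytest.approx(9e-3, abs=1e-9)

    def test_out_of_range_points_rejected(self):
        with pytest.raises(ParameterError):
            default_baseline_window(time_grid(1.0, 1e-3), None, n_points=2)
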