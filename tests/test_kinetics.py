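import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boutonkit.core import ProtocolError, Trace
from boutonkit.kinetics import (
    area_under_curve,
    fit_decay,
    fit_linear_range,
    fit_sigmoid,
    measure_initial_slope,
    measure_peak,
    summarize_kinetics,
)


def norm_trace(t, y):
    return Trace(np.asarray(t, float), np.asarray(y, float),
                 stage="normalized", f0=1.0)


class TestPeak:
    def test_flat_trace_zero_peak(self):
        t = np.arange(-5, 20) * 0.1
        peak, ttp = measure_peak(norm_trace(t, np.ones(t.size)), 0.0)
        assert peak == 0.0

    def test_simple_arithmetic(self):
        tr = norm_trace([0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.4, 1.2])
        peak, ttp = measure_peak(tr, 1.5)
        assert peak == pytest.approx(0.4)
        assert ttp == pytest.approx(0.5)

    def test_tie_takes_earliest(self):
        tr = norm_trace([0, 1, 2, 3], [1.0, 1.3, 1.3, 1.0])
        _, ttp = measure_peak(tr, 0.0)
        assert ttp == 1.0

    def test_no_post_onset_samples_rejected(self):
        with pytest.raises(ProtocolError):
            measure_peak(norm_trace([0.0, 1.0], [1.0, 1.0]), 5.0)


class TestInitialSlope:
    def test_flat_trace(self):
        t = np.arange(10) * 0.1
        assert measure_initial_slope(norm_trace(t, np.ones(10)), 0.0) == 0.0

    def test_exact_linear_rise(self):
        t = np.arange(10) * 0.1
        assert measure_initial_slope(
            norm_trace(t, 1.0 + 0.5 * t), 0.0, n_points=5
        ) == pytest.approx(0.5, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=10))
    def test_matches_normal_equations(self, seed, n_points):
        rng = np.random.default_rng(seed)
        t = np.arange(20) * 0.1
        y = rng.uniform(0.5, 2.0, 20)
        slope = measure_initial_slope(norm_trace(t, y), 0.0, n_points)
        ts, ys = t[:n_points], y[:n_points]
        n = n_points
        oracle = ((n * np.sum(ts * ys) - ts.sum() * ys.sum())
                  / (n * np.sum(ts ** 2) - ts.sum() ** 2))
        assert slope == pytest.approx(oracle, abs=1e-9)


class TestAUC:
    def test_flat_trace_zero(self):
        t = np.arange(-5, 30) * 0.1
        assert area_under_curve(norm_trace(t, np.ones(t.size)), 0.0) == 0.0

    def test_constant_rectangle(self):
        t = np.arange(-5, 30) * 0.1
        y = np.where(t >= -0.05, 1.5, 1.0)
        assert area_under_curve(norm_trace(t, y), 0.0, 2.0) == \
            pytest.approx(1.0, abs=1e-9)

    def test_linearity_under_amplitude_doubling(self, rng):
        t = np.arange(-5, 30) * 0.1
        bump = np.where(t >= 0, rng.random(t.size), 0.0)
        a1 = area_under_curve(norm_trace(t, 1 + bump), 0.0)
        a2 = area_under_curve(norm_trace(t, 1 + 2 * bump), 0.0)
        assert a2 == pytest.approx(2 * a1, abs=1e-9)

    def test_window_must_be_covered(self):
        t = np.arange(10) * 0.1
        with pytest.raises(ProtocolError):
            area_under_curve(norm_trace(t, np.ones(10)), 0.0, 2.0)


class TestTimeShiftInvariance:
    def test_peak_auc_slope_shift_invariant(self, rng):
        t = np.arange(-10, 40) * 0.1
        y = 1.0 + np.where(t >= 0, np.exp(-t / 0.7), 0.0) \
            + rng.normal(0, 0.01, t.size)
        for shift in (0.0, 3.7, -1.2):
            tr = norm_trace(t + shift, y)
            assert measure_peak(tr, shift)[0] == pytest.approx(
                measure_peak(norm_trace(t, y), 0.0)[0], abs=1e-12)
            assert area_under_curve(tr, shift) == pytest.approx(
                area_under_curve(norm_trace(t, y), 0.0), abs=1e-9)
            assert measure_initial_slope(tr, shift) == pytest.approx(
                measure_initial_slope(norm_trace(t, y), 0.0), abs=1e-9)


class TestDecayFit:
    def test_noiseless_single_exponential(self):
        t = np.arange(0, 60) * 0.098
        fit = fit_decay(norm_trace(t, 1 + 0.8 * np.exp(-t / 0.5)), 0.0)
        assert fit.model == "single"
        assert fit.fast_tau_s == pytest.approx(0.5, rel=0.01)

    def test_noiseless_double_exponential(self):
        t = np.arange(0, 120) * 0.098
        y = 1 + 0.5 * np.exp(-t / 0.3) + 0.5 * np.exp(-t / 3.0)
        fit = fit_decay(norm_trace(t, y), 0.0)
        assert fit.model == "double"
        assert fit.fast_tau_s == pytest.approx(0.3, rel=0.05)

    def test_noisy_fast_tau_spot_check(self):
        """SNR 10 single exponential: tau within 10% for most seeds
        (the full 20-seed medians run in the acceptance suite)."""
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = np.arange(0, 120) * (0.5 / 20)
            y = 1 + 1.0 * np.exp(-t / 0.5) + rng.normal(0, 0.1, t.size)
            fit = fit_decay(norm_trace(t, y), 0.0)
            errs.append(abs(fit.fast_tau_s - 0.5) / 0.5)
        assert np.median(errs) <= 0.10

    def test_fast_tau_is_min(self):
        t = np.arange(0, 120) * 0.098
        y = 1 + 0.5 * np.exp(-t / 0.3) + 0.5 * np.exp(-t / 3.0)
        fit = fit_decay(norm_trace(t, y), 0.0)
        assert fit.fast_tau_s == min(fit.taus_s)


class TestSummary:
    def test_summary_consistency(self):
        t = np.arange(-10, 60) * 0.098
        y = 1 + np.where(t >= 0, 0.6 * np.exp(-t / 0.5), 0.0)
        s = summarize_kinetics(norm_trace(t, y), 0.0)
        assert s.peak == pytest.approx(0.6, abs=1e-9)
        assert s.time_to_peak_s == pytest.approx(0.0)
        assert s.fast_tau_s == pytest.approx(0.5, rel=0.05)
        assert s.auc > 0


class TestSigmoid:
    def test_noiseless_parameter_recovery(self):
        x = np.linspace(0, 70, 15)
        y = 0.0 + (1.0 - 0.0) / (1 + np.exp((30.0 - x) / 5.0))
        fit = fit_sigmoid(x, y)
        assert fit.base == pytest.approx(0.0, abs=0.02)
        assert fit.top == pytest.approx(1.0, rel=0.02)
        assert fit.x50 == pytest.approx(30.0, rel=0.02)
        assert fit.rate == pytest.approx(5.0, rel=0.02)

    def test_constant_response_flagged_degenerate(self):
        fit = fit_sigmoid(np.linspace(0, 10, 8), np.full(8, 2.0))
        assert fit.degenerate
        assert fit.top == pytest.approx(fit.base)

    def test_symmetric_data_centers_x50(self):
        x = np.linspace(10, 50, 21)
        y = 1.0 / (1 + np.exp((30.0 - x) / 4.0))
        fit = fit_sigmoid(x, y)
        assert fit.x50 == pytest.approx(30.0, abs=1e-6)


class TestLinearRange:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear_range(x, 2 * x + 1, x_max=100.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_cutoff_restricts_points(self):
        x = np.array([1.0, 2.0, 60.0, 70.0])
        y = np.array([1.0, 2.0, 100.0, -50.0])
        fit = fit_linear_range(x, y, x_max=50.0)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, 20)
        y = rng.uniform(-5, 5, 20)
        fit = fit_linear_range(x, y, x_max=80.0)
        keep = x < 80.0
        xs, ys = x[keep], y[keep]
        n = keep.sum()
        sl = ((n * np.sum(xs * ys) - xs.sum() * ys.sum())
              / (n * np.sum(xs ** 2) - xs.sum() ** 2))
        ic = ys.mean() - sl * xs.mean()
        assert fit.slope == pytest.approx(sl, abs=1e-9)
        assert fit.intercept == pytest.approx(ic, abs=1e-9)
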