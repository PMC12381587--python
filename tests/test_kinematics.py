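import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silkflight.kinematics import (
    FourierWaveform,
    fit_fourier,
    fit_fourier_with_trend,
    phase_difference,
    rescale_waveform,
    waveform_stats,
)


def wf(a0=0.0, a=(0, 0, 0), b=(0, 0, 0), f=10.0):
    return FourierWaveform(a0=a0, a=np.array(a, float), b=np.array(b, float), f=f)


class TestEvaluation:
    def test_constant_and_derivatives(self):
        c = wf(a0=5.0)
        assert c(0.123) == pytest.approx(5.0)
        assert c(0.123, deriv=1) == 0.0
        assert c(0.123, deriv=2) == 0.0

    def test_second_derivative_of_fundamental(self):
        w = wf(a=(2.0, 0, 0), f=7.0)
        assert w(0.0, deriv=2) == pytest.approx(-((2 * np.pi * 7) ** 2) * 2.0)

    def test_periodicity(self):
        w = wf(a0=1.0, a=(1.0, 0.3, 0.1), b=(0.2, -0.4, 0.05), f=13.0)
        t = np.linspace(0, 0.07, 11)
        np.testing.assert_allclose(w(t), w(t + 1 / 13.0), atol=1e-12)

    def test_derivative_matches_finite_difference(self):
        w = wf(a0=1.0, a=(1.0, 0.3, 0.1), b=(0.2, -0.4, 0.05), f=13.0)
        t, h = 0.0123, 1e-6
        fd1 = (w(t + h) - w(t - h)) / (2 * h)
        fd2 = (w(t + h) - 2 * w(t) + w(t - h)) / h**2
        assert w(t, deriv=1) == pytest.approx(fd1, rel=1e-7)
        assert w(t, deriv=2) == pytest.approx(fd2, rel=1e-4)

    def test_antiderivative_matches_quadrature(self):
        w = wf(a0=2.0, a=(1.0, 0.3, 0.0), b=(0.0, 0.1, -0.2), f=5.0)
        t = 0.31
        grid = np.linspace(0, t, 20001)
        num = np.trapezoid(w(grid), grid)
        assert w.antiderivative(t) - w.antiderivative(0.0) == pytest.approx(num, abs=1e-8)


class TestFitting:
    def test_exact_recovery_of_known_series(self):
        truth = wf(a0=3.0, a=(1.0, -0.5, 0.25), b=(0.8, 0.1, -0.3), f=12.0)
        t = np.linspace(0, 1 / 12.0, 40, endpoint=False)
        fitted = fit_fourier(t, truth(t), f=12.0, K=3)
        np.testing.assert_allclose(fitted.a, truth.a, atol=1e-10)
        np.testing.assert_allclose(fitted.b, truth.b, atol=1e-10)
        assert fitted.a0 == pytest.approx(3.0, abs=1e-10)

    def test_constant_samples(self):
        t = np.linspace(0, 0.2, 30)
        fitted = fit_fourier(t, np.full_like(t, 4.2), f=10.0, K=3)
        assert fitted.a0 == pytest.approx(4.2)
        np.testing.assert_allclose(fitted.a, 0, atol=1e-10)
        np.testing.assert_allclose(fitted.b, 0, atol=1e-10)

    def test_noisy_fit_equals_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        truth = wf(a0=1.0, a=(0.9, 0.2, 0.05), b=(0.4, -0.1, 0.02), f=8.0)
        t = np.linspace(0, 0.25, 120)
        y = truth(t) + rng.normal(0, 0.1, t.size)
        fitted = fit_fourier(t, y, f=8.0, K=3)
        # independent solve of the normal equations
        k = np.arange(1, 4)
        arg = np.outer(t, 2 * np.pi * k * 8.0)
        A = np.hstack([np.ones((t.size, 1)), np.cos(arg), np.sin(arg)])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(
            np.concatenate([[fitted.a0], fitted.a, fitted.b]), coef, atol=1e-9
        )

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fit_fourier([0, 0.01, 0.02], [1, 2, 3], f=10.0, K=3)

    def test_trend_fit_recovers_slope(self):
        truth = wf(a=(0.5, 0.1, 0.0), b=(0.2, 0.0, 0.1), f=9.0)
        t = np.linspace(0, 0.5, 300)
        y = 1.5 + 2.5 * t + truth(t)
        slope, fitted = fit_fourier_with_trend(t, y, f=9.0, K=3)
        assert slope == pytest.approx(2.5, abs=1e-9)
        np.testing.assert_allclose(fitted.a, truth.a, atol=1e-9)


class TestStats:
    def test_cosine_mean_amplitude(self):
        w = FourierWaveform.cosine(mean=2.0, half_amp=3.0, f=10.0)
        mean, amp = waveform_stats(w)
        assert mean == pytest.approx(2.0, abs=1e-9)
        assert amp == pytest.approx(6.0, rel=1e-5)

    def test_constant(self):
        mean, amp = waveform_stats(wf(a0=7.0))
        assert (mean, amp) == (7.0, 0.0)

    def test_two_harmonic_amplitude_vs_dense_scan(self):
        w = wf(a=(1.0, 0.4, 0.0), b=(0.0, 0.3, 0.0), f=6.0)
        _, amp = waveform_stats(w, n_grid=1024)
        t = np.arange(10**6) / (10**6 * 6.0)
        y = w(t)
        assert amp == pytest.approx(y.max() - y.min(), abs=1e-4)


class TestRescale:
    def test_identity(self):
        w = wf(a0=1.0, a=(1.0, 0.2, 0.1), b=(0.3, 0.0, 0.0), f=10.0)
        mean, amp = waveform_stats(w)
        w2 = rescale_waveform(w, mean, amp)
        np.testing.assert_allclose(w2.a, w.a, rtol=1e-12)
        assert w2.a0 == pytest.approx(w.a0)

    def test_zero_amplitude_gives_constant(self):
        w = wf(a=(1.0, 0.2, 0.0), f=10.0)
        w2 = rescale_waveform(w, new_mean=4.0, new_amplitude=0.0)
        assert w2.a0 == 4.0
        assert np.all(w2.a == 0) and np.all(w2.b == 0)

    def test_cosine_to_amplitude_ten(self):
        w = wf(a=(1.0, 0, 0), f=10.0)
        w2 = rescale_waveform(w, new_mean=0.0, new_amplitude=10.0)
        assert w2.a[0] == pytest.approx(5.0, rel=1e-6)

    def test_degenerate_source_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rescale_waveform(wf(a0=1.0), new_mean=0.0, new_amplitude=1.0)

    def test_stats_hit_target_within_1e9(self):
        w = wf(a0=-2.0, a=(0.7, 0.2, -0.1), b=(0.1, 0.4, 0.0), f=11.0)
        w2 = rescale_waveform(w, new_mean=33.0, new_amplitude=120.0)
        mean, amp = waveform_stats(w2)
        assert mean == pytest.approx(33.0, abs=1e-9)
        assert amp == pytest.approx(120.0, abs=1e-9)


class TestPhase:
    def test_cos_vs_sin_quarter_period(self):
        cos_w = wf(a=(1.0, 0, 0), f=10.0)
        sin_w = wf(b=(1.0, 0, 0), f=10.0)
        assert phase_difference(cos_w, sin_w) == pytest.approx(90.0)

    def test_self_is_zero(self):
        w = wf(a=(0.5, 0.2, 0.0), b=(0.5, 0, 0), f=10.0)
        assert phase_difference(w, w) == pytest.approx(0.0)

    def test_half_period_shift_is_180(self):
        w = wf(a=(0.7, 0.2, 0.1), b=(0.3, -0.1, 0.0), f=10.0)
        assert phase_difference(w, w.half_period_shifted()) == pytest.approx(180.0)

    def test_zero_fundamental_rejected(self):
        with pytest.raises(ValueError, match="fundamental"):
            phase_difference(wf(a=(0, 1.0, 0), f=10.0), wf(a=(1, 0, 0), f=10.0))

    def test_invariant_to_amplitude_rescale(self):
        a = wf(a0=1.0, a=(0.8, 0.1, 0.0), b=(0.4, 0.0, 0.1), f=10.0)
        b = wf(a0=0.0, a=(0.1, 0.0, 0.0), b=(0.9, 0.2, 0.0), f=10.0)
        d0 = phase_difference(a, b)
        a2 = rescale_waveform(a, 5.0, 44.0)
        assert phase_difference(a2, b) == pytest.approx(d0, abs=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a0=st.floats(-50, 50),
    coeffs=st.lists(st.floats(-10, 10), min_size=6, max_size=6),
    f=st.floats(5.0, 30.0),
)
def test_fit_eval_duality(a0, coeffs, f):
    """Fitting samples of an order-3 series at its own frequency returns
    the same series."""
    truth = FourierWaveform(a0=a0, a=np.array(coeffs[:3]), b=np.array(coeffs[3:]), f=f)
    t = np.arange(64) / (64 * f)
    fitted = fit_fourier(t, truth(t), f=f, K=3)
    np.testing.assert_allclose(fitted.a, truth.a, atol=1e-8)
    np.testing.assert_allclose(fitted.b, truth.b, atol=1e-8)
    assert fitted.a0 == pytest.approx(a0, abs=1e-8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    mean=st.floats(-80, 80),
    amp=st.floats(0.1, 200),
    phase=st.floats(0, 360),
)
def test_rescale_reaches_any_target(mean, amp, phase):
    base = FourierWaveform.cosine(0.0, 1.0, f=12.0, phase_deg=phase)
    out = rescale_waveform(base, mean, amp)
    m, a = waveform_stats(out)
    assert m == pytest.approx(mean, abs=1e-9)
    assert a == pytest.approx(amp, rel=1e-6)
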