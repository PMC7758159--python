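import numpy as np
import pytest
from scipy import signal as scsig

from nervequant.errors import DataError, ParameterError
from nervequant.preprocess import (
    BURST_BAND,
    SPIKE_BAND,
    FilterSpec,
    bandpass_filter,
    bandpass_sos,
    bp_bin_summary,
    notch_filter,
    rectify_integrate,
)

FS = 4000.0
SSNA_SPEC = FilterSpec(kind="bandpass", low_hz=SPIKE_BAND[0], high_hz=SPIKE_BAND[1])


def analytic_gain_db(sos, f, fs, zero_phase=True):
    """Frequency-response oracle: gain of the designed filter at f Hz."""
    _, h = scsig.sosfreqz(sos, worN=[f], fs=fs)
    g = np.abs(h[0])
    if zero_phase:  # forward-backward application squares the magnitude
        g = g**2
    return 20 * np.log10(g)


def steady_rms_ratio(filtered, x, fs, settle_s=0.25):
    n = int(settle_s * fs)
    return np.sqrt(np.mean(filtered[n:-n] ** 2)) / np.sqrt(np.mean(x[n:-n] ** 2))


class TestBandpass:
    def test_inband_650hz_passes(self):
        sos = bandpass_sos(FS, SSNA_SPEC)
        assert analytic_gain_db(sos, 650.0, FS) > -1.0
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 650 * t)
        y = bandpass_filter(x, FS, SSNA_SPEC)
        assert steady_rms_ratio(y, x, FS) >= 0.9

    def test_10hz_attenuated(self):
        sos = bandpass_sos(FS, SSNA_SPEC)
        assert analytic_gain_db(sos, 10.0, FS) <= -20.0
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass_filter(x, FS, SSNA_SPEC)
        assert steady_rms_ratio(y, x, FS) <= 10 ** (-20 / 20)

    def test_cvna_band_valid(self):
        spec = FilterSpec(kind="bandpass", low_hz=BURST_BAND[0], high_hz=BURST_BAND[1])
        sos = bandpass_sos(FS, spec)
        assert analytic_gain_db(sos, 400.0, FS) > -1.0
        assert analytic_gain_db(sos, 1500.0, FS) < -20.0

    def test_zero_in_zero_out(self):
        y = bandpass_filter(np.zeros(4000), FS, SSNA_SPEC)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_band_edge_at_nyquist_rejected(self):
        spec = FilterSpec(kind="bandpass", low_hz=300.0, high_hz=2500.0)
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros(4000), FS, spec)

    def test_linearity(self, rng):
        x = rng.normal(size=8000)
        y = rng.normal(size=8000)
        lhs = bandpass_filter(2.0 * x + 3.0 * y, FS, SSNA_SPEC)
        rhs = 2.0 * bandpass_filter(x, FS, SSNA_SPEC) + 3.0 * bandpass_filter(
            y, FS, SSNA_SPEC
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_zero_phase_no_group_delay(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 650 * t)
        y = bandpass_filter(x, FS, SSNA_SPEC)
        n = len(x) // 2
        lags = scsig.correlation_lags(n, n, mode="full")
        xc = scsig.correlate(y[n // 2 : n // 2 + n], x[n // 2 : n // 2 + n], mode="full")
        assert lags[np.argmax(xc)] == 0

    def test_causal_mode_has_delay_free_energy(self):
        spec = FilterSpec(
            kind="bandpass", low_hz=300.0, high_hz=1000.0, zero_phase=False
        )
        x = np.zeros(4000)
        x[0] = 1.0
        y = bandpass_filter(x, FS, spec)
        assert y.shape == x.shape


class TestNotch:
    def test_50hz_attenuated(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 50 * t)
        y = notch_filter(x, FS, 50.0, 30.0)
        assert steady_rms_ratio(y, x, FS, settle_s=1.0) <= 10 ** (-20 / 20)

    def test_analytic_response(self):
        b, a = scsig.iirnotch(50.0, 30.0, fs=FS)
        _, h = scsig.freqz(b, a, worN=[50.0, 400.0], fs=FS)
        assert 20 * np.log10(np.abs(h[0]) ** 2) <= -20.0  # zero-phase squared
        assert abs(20 * np.log10(np.abs(h[1]) ** 2)) <= 1.0

    def test_400hz_unity(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 400 * t)
        y = notch_filter(x, FS, 50.0, 30.0)
        ratio = steady_rms_ratio(y, x, FS)
        assert abs(20 * np.log10(ratio)) <= 1.0

    def test_zero_input(self):
        np.testing.assert_allclose(notch_filter(np.zeros(4000), FS), 0.0, atol=1e-12)

    def test_center_beyond_nyquist(self):
        with pytest.raises(ParameterError):
            notch_filter(np.zeros(100), FS, 3000.0)


class TestRectifyIntegrate:
    def test_impulse_efold_decay(self):
        x = np.zeros(4000)
        n0 = 100
        x[n0] = 1.0
        env = rectify_integrate(x, FS, tau=0.1)
        at_impulse = env.samples[n0]
        after_tau = env.samples[n0 + 400]  # 0.1 s later at 4 kHz
        assert at_impulse > 0
        np.testing.assert_allclose(after_tau / at_impulse, np.exp(-1.0), rtol=1e-6)

    def test_constant_converges_to_itself(self):
        c = 7.5
        x = np.full(int(2 * FS), c)  # 2 s = 20 tau
        env = rectify_integrate(x, FS, tau=0.1)
        np.testing.assert_allclose(env.samples[-1], c, rtol=1e-6)

    def test_sign_flip_invariance(self, rng):
        x = rng.normal(size=4000)
        a = rectify_integrate(x, FS).samples
        b = rectify_integrate(-x, FS).samples
        np.testing.assert_array_equal(a, b)

    def test_nonnegative_output(self, rng):
        env = rectify_integrate(rng.normal(size=4000), FS)
        assert np.all(env.samples >= 0)

    def test_monotone_in_pointwise_magnitude(self, rng):
        x = rng.normal(size=4000)
        bigger = x * 1.5
        a = rectify_integrate(x, FS).samples
        b = rectify_integrate(bigger, FS).samples
        assert np.all(b >= a - 1e-12)

    def test_bad_tau(self):
        with pytest.raises(ParameterError):
            rectify_integrate(np.zeros(10), FS, tau=0.0)


class TestBpBinSummary:
    def test_constant(self):
        out = bp_bin_summary(np.full(int(600 * 10), 100.0), fs=10.0, bin_s=600.0)
        assert out == [(100.0, 0.0)]

    def test_two_complete_bins(self):
        out = bp_bin_summary(np.zeros(int(1200 * 10)), fs=10.0, bin_s=600.0)
        assert len(out) == 2

    def test_partial_bin_flagged(self):
        with pytest.warns(UserWarning, match="bin"):
            out = bp_bin_summary(np.zeros(int(900 * 10)), fs=10.0, bin_s=600.0)
        assert len(out) == 1

    def test_sine_sd(self):
        a = 12.0
        t = np.arange(int(600 * 100)) / 100.0
        x = 100.0 + a * np.sin(2 * np.pi * 1.0 * t)
        ((mean, sd),) = bp_bin_summary(x, fs=100.0, bin_s=600.0)
        np.testing.assert_allclose(sd, a / np.sqrt(2), rtol=0.01)
        np.testing.assert_allclose(mean, 100.0, atol=0.01)

    def test_empty(self):
        with pytest.raises(DataError):
            bp_bin_summary(np.array([]), fs=10.0)
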