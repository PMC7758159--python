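import numpy as np
import pytest

from nervequant.errors import DataError, DegenerateDataWarning, ParameterError
from nervequant.io_timeseries import Annotation
from nervequant.preprocess import FilterSpec, bandpass_filter, notch_filter
from nervequant.spikes import (
    NoiseEstimate,
    SpikeEvent,
    amplitude_gain,
    bin_firing_frequency,
    detect_spikes,
    estimate_noise_floor,
    mad_sd,
)
from nervequant.synthetic import SynthConfig, simulate_session

FS = 4000.0


class TestNoiseFloor:
    def test_gaussian_sd_recovery(self, noise_recording):
        est = estimate_noise_floor(
            noise_recording.channel("nerve"),
            noise_recording.fs,
            noise_recording.annotation("postmortem"),
        )
        np.testing.assert_allclose(est.floor, 2.0, rtol=0.05)
        assert est.method == "mad"
        assert est.n_samples == noise_recording.n_samples

    def test_all_zero_segment_warns(self):
        with pytest.warns(DegenerateDataWarning):
            est = estimate_noise_floor(np.zeros(int(2 * FS)), FS)
        assert est.floor == 0.0

    def test_outlier_robustness(self, rng):
        x = rng.normal(0, 1.0, int(10 * FS))
        clean = estimate_noise_floor(x, FS).floor
        x_out = x.copy()
        x_out[1234] = 1e6
        contaminated = estimate_noise_floor(x_out, FS).floor
        # MAD barely moves where the plain sd explodes
        np.testing.assert_allclose(contaminated, clean, rtol=1e-3)
        assert np.std(x_out) > 10 * np.std(x)

    def test_segment_too_short(self):
        with pytest.raises(DataError):
            estimate_noise_floor(np.zeros(100), FS)

    def test_segment_outside_trace(self):
        with pytest.raises(DataError):
            estimate_noise_floor(np.zeros(int(2 * FS)), FS, Annotation("seg", 1.0, 3.0))


def _ssna_filter(trace, fs):
    spec = FilterSpec(kind="bandpass", low_hz=300.0, high_hz=1000.0)
    return notch_filter(bandpass_filter(trace, fs, spec), fs, 50.0, 30.0)


def _match(detected, truth, tol):
    """Greedy one-to-one matching of event times; returns (tp, fp, fn)."""
    det = np.array(detected, dtype=float)
    used = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in truth:
        if det.size == 0:
            break
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            tp += 1
            used[j] = True
    return tp, det.size - tp, len(truth) - tp


class TestDetectSpikes:
    def test_recovery_on_seeded_simulation(self):
        # 60 s, ~30 spikes of 8x noise sd; floor taken from the raw tail.
        cfg = SynthConfig(
            duration_s=60.0, burst_rate=0.0, tonic_rate=0.5, spike_peak=16.0,
            noise_sd=2.0, spike_width_ms=2.0, seed=42,
        )
        rec, truth = simulate_session(cfg, postmortem_s=30.0)
        filt = _ssna_filter(rec.channel("nerve"), rec.fs)
        noise = estimate_noise_floor(
            rec.channel("nerve"), rec.fs, rec.annotation("postmortem")
        )
        events = detect_spikes(filt, rec.fs, noise, k=3.0, refractory_s=0.002)
        det = [e.t for e in events if e.t < 60.0]
        tp, fp, fn = _match(det, truth.spike_times, tol=0.004)
        assert tp / len(truth.spike_times) >= 0.95
        assert tp / len(det) >= 0.95

    def test_noise_only_false_positive_rate(self, rng):
        # raw-baseline floor, k = 3, filtered trace: well under 60/min
        raw = rng.normal(0, 2.0, int(60 * FS))
        filt = _ssna_filter(raw, FS)
        noise = estimate_noise_floor(raw, FS)
        events = detect_spikes(filt, FS, noise, k=3.0, refractory_s=0.001)
        assert len(events) <= 60

    def test_k_above_max_gives_no_events(self, rng):
        x = rng.normal(0, 1.0, int(2 * FS))
        noise = NoiseEstimate(floor=1.0, method="mad", source_annotation="x", n_samples=100)
        k = float(np.max(np.abs(x))) / noise.floor + 1.0
        assert detect_spikes(x, FS, noise, k=k) == []

    def test_zero_floor_rejected(self):
        noise = NoiseEstimate(floor=0.0, method="mad", source_annotation="x", n_samples=100)
        with pytest.raises(DataError):
            detect_spikes(np.zeros(100), FS, noise)

    def test_k_below_one_rejected(self):
        noise = NoiseEstimate(floor=1.0, method="mad", source_annotation="x", n_samples=100)
        with pytest.raises(ParameterError):
            detect_spikes(np.zeros(100), FS, noise, k=0.5)

    def test_scale_equivariance(self, rng):
        x = rng.normal(0, 1.0, int(5 * FS))
        noise = NoiseEstimate(floor=1.0, method="mad", source_annotation="x", n_samples=100)
        a = detect_spikes(x, FS, noise, k=2.0)
        noise_c = NoiseEstimate(floor=7.0, method="mad", source_annotation="x", n_samples=100)
        b = detect_spikes(7.0 * x, FS, noise_c, k=2.0)
        assert [e.t for e in a] == [e.t for e in b]
        np.testing.assert_allclose([e.peak * 7.0 for e in a], [e.peak for e in b])

    def test_monotone_in_k(self, rng):
        x = rng.normal(0, 1.0, int(5 * FS))
        noise = NoiseEstimate(floor=1.0, method="mad", source_annotation="x", n_samples=100)
        counts = [len(detect_spikes(x, FS, noise, k=k)) for k in (1.0, 2.0, 3.0, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_refractory_enforced(self):
        x = np.zeros(int(FS))
        for i in (1000, 1002, 1004):
            x[i] = 10.0
        noise = NoiseEstimate(floor=1.0, method="mad", source_annotation="x", n_samples=100)
        events = detect_spikes(x, FS, noise, k=3.0, refractory_s=0.01)
        assert len(events) == 1


class TestBinning:
    def test_count_in_one_bin(self):
        spikes = [SpikeEvent(t=i, peak=1.0) for i in np.linspace(0, 599.9, 600)]
        bins = bin_firing_frequency(spikes, (0.0, 600.0))
        assert len(bins) == 1
        assert bins[0].firing_frequency == 600
        assert bins[0].rate_hz == 1.0

    def test_boundary_spike_goes_to_later_bin(self):
        spikes = [SpikeEvent(t=600.0, peak=1.0)]
        bins = bin_firing_frequency(spikes, (0.0, 1200.0))
        assert [b.n_spikes for b in bins] == [0, 1]

    def test_empty_spike_list(self):
        bins = bin_firing_frequency([], (0.0, 1800.0))
        assert [b.n_spikes for b in bins] == [0, 0, 0]

    def test_conservation(self, rng):
        times = rng.uniform(0.0, 1800.0, 500)
        spikes = [SpikeEvent(t=float(t), peak=1.0) for t in times]
        bins = bin_firing_frequency(spikes, (0.0, 1800.0))
        assert sum(b.n_spikes for b in bins) == 500

    def test_incomplete_trailing_bin_excluded(self):
        spikes = [SpikeEvent(t=650.0, peak=1.0)]
        bins = bin_firing_frequency(spikes, (0.0, 900.0))
        assert len(bins) == 1  # [600, 900) is incomplete

    def test_bad_bin(self):
        with pytest.raises(ParameterError):
            bin_firing_frequency([], (0.0, 600.0), bin_s=0.0)


class TestAmplitudeGain:
    NOISE = NoiseEstimate(floor=2.0, method="mad", source_annotation="x", n_samples=100)

    def test_uniform_peaks(self):
        spikes = [SpikeEvent(t=i, peak=10.0) for i in range(5)]
        assert amplitude_gain(spikes, self.NOISE) == 5.0

    def test_mixed_peaks(self):
        spikes = [SpikeEvent(t=0.0, peak=4.0), SpikeEvent(t=1.0, peak=8.0)]
        assert amplitude_gain(spikes, self.NOISE) == 3.0

    def test_empty_is_missing_not_zero(self):
        assert amplitude_gain([], self.NOISE) is None

    def test_zero_floor(self):
        bad = NoiseEstimate(floor=0.0, method="mad", source_annotation="x", n_samples=100)
        with pytest.raises(DataError):
            amplitude_gain([SpikeEvent(t=0.0, peak=1.0)], bad)


def test_mad_sd_gaussian(rng):
    np.testing.assert_allclose(mad_sd(rng.normal(0, 3.0, 200_000)), 3.0, rtol=0.02)
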